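"""Evaluation metrics: relative difference, FOM, EIF, order tables,
replicate standard deviations."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sampling import SampleStream
from .transport import (ScatterImage, Scene, TransportTables,
                        estimate_scatter, upsample_probability)


def relative_difference(reference: np.ndarray, test: np.ndarray) -> float:
    """||r - t||_2 / ||r||_2 over all pixels."""
    r = np.asarray(reference, dtype=float)
    t = np.asarray(test, dtype=float)
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch {r.shape} vs {t.shape}")
    norm = np.linalg.norm(r)
    if norm == 0:
        raise ZeroDivisionError("zero reference image")
    return float(np.linalg.norm(r - t) / norm)


def figure_of_merit(t_minutes: float, sigma: float) -> float:
    """FOM = 1 / (T sigma^2), T in minutes."""
    if t_minutes <= 0 or sigma <= 0:
        raise ValueError("T and sigma must be > 0")
    return 1.0 / (t_minutes * sigma * sigma)


def efficiency_improvement(fom_a: float, fom_ref: float) -> float:
    """EIF = FOM_A / FOM_reference."""
    if fom_a <= 0 or fom_ref <= 0:
        raise ValueError("FOMs must be > 0")
    return fom_a / fom_ref


@dataclass(frozen=True)
class OrderTableRow:
    order: int
    value: float
    fraction: float
    cumulative: float


def order_table(image: ScatterImage, pixel: tuple | None = None,
                full_shape=(512, 512)) -> list[OrderTableRow]:
    """Per-order contributions at one detector pixel, or detector-wide.

    ``pixel=(ju, jv)`` indexes the *full-resolution* grid; when the image
    was accumulated on a coarse grid it is first upsampled (bilinearly,
    conserving total probability).  ``pixel=None`` sums each order over
    the whole detector.  Fractions are of the summed total and sum to 1
    over the included orders.
    """
    if pixel is None:
        values = image.per_order.sum(axis=(1, 2))
    else:
        ju, jv = pixel
        nu, nv = image.per_order.shape[1:]
        if (nu, nv) == tuple(full_shape):
            values = image.per_order[:, ju, jv]
        else:
            values = np.array([
                upsample_probability(sl, full_shape)[ju, jv]
                for sl in image.per_order])
    total = values.sum()
    if total <= 0:
        raise ValueError("empty scatter image")
    rows = []
    cum = 0.0
    for i, v in enumerate(values, start=1):
        cum += float(v)
        rows.append(OrderTableRow(i, float(v), float(v / total), cum))
    return rows


def replicate_sigma(scene: Scene, n_histories: int, replicates: int,
                    kind: str = "sobol", seed: int = 0,
                    scrambles=None,
                    tables: TransportTables | None = None,
                    return_values: bool = False):
    """Replicate standard deviation of the total detected scatter.

    Runs ``replicates`` independent estimates (distinct scramble ids for
    Sobol', distinct substream seeds for pseudorandom), summarizes each
    by the total detected scatter probability over all pixels and
    orders, and returns the sample standard deviation.  ``scrambles``
    overrides the per-replicate randomization ids (e.g. ``[None] * R``
    replays the identical unscrambled sequence, giving sigma = 0).
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    if scrambles is None:
        scrambles = range(replicates)
    tables = tables or TransportTables(scene)
    values = np.empty(replicates)
    for r, sc in zip(range(replicates), scrambles):
        stream = SampleStream(kind, scene.dimension, seed, scramble=sc)
        img = estimate_scatter(scene, n_histories, stream, tables=tables)
        values[r] = img.total_probability
    sigma = float(np.std(values, ddof=1))
    if return_values:
        return sigma, values
    return sigma
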