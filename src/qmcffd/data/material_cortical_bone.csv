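energy_keV,mu_pe_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.60000000e+01,1.59194366e+00,3.73042213e-02,4.20715907e-02
1.65558518e+01,1.43202269e+00,3.72307678e-02,3.96651129e-02
1.71310142e+01,1.28816681e+00,3.71551658e-02,3.73829689e-02
1.77261583e+01,1.15876217e+00,3.70773659e-02,3.52198417e-02
1.83419781e+01,1.04235706e+00,3.69973179e-02,3.31705406e-02
1.89791919e+01,9.37645596e-01,3.69149720e-02,3.12300131e-02
1.96385430e+01,8.43453070e-01,3.68302777e-02,2.93933541e-02
2.03208004e+01,7.58722788e-01,3.67431848e-02,2.76558107e-02
2.10267600e+01,6.82504207e-01,3.66536429e-02,2.60127857e-02
2.17572451e+01,6.13942273e-01,3.65616017e-02,2.44598384e-02
2.25131078e+01,5.52267825e-01,3.64670109e-02,2.29926842e-02
2.32952297e+01,4.96788973e-01,3.63698208e-02,2.16071936e-02
2.41045232e+01,4.46883327e-01,3.62699817e-02,2.02993896e-02
2.49419320e+01,4.01991025e-01,3.61674444e-02,1.90654457e-02
2.58084331e+01,3.61608443e-01,3.60621603e-02,1.79016823e-02
2.67050371e+01,3.25282550e-01,3.59540815e-02,1.68045642e-02
2.76327897e+01,2.92605827e-01,3.58431608e-02,1.57706967e-02
2.85927732e+01,2.63211691e-01,3.57293517e-02,1.47968230e-02
2.95861071e+01,2.36770385e-01,3.56126091e-02,1.38798203e-02
3.06139503e+01,2.12985278e-01,3.54928886e-02,1.30166971e-02
3.16775014e+01,1.91589538e-01,3.53701473e-02,1.22045894e-02
3.27780012e+01,1.72343138e-01,3.52443438e-02,1.14407575e-02
3.39167330e+01,1.55030162e-01,3.51154380e-02,1.07225832e-02
3.50950253e+01,1.39456386e-01,3.49833916e-02,1.00475656e-02
3.63142523e+01,1.25447095e-01,3.48481683e-02,9.41331888e-03
3.75758362e+01,1.12845128e-01,3.47097334e-02,8.81756802e-03
3.88812484e+01,1.01509110e-01,3.45680548e-02,8.25814600e-03
4.02320115e+01,9.13118673e-02,3.44231023e-02,7.73299026e-03
4.16297012e+01,8.21390033e-02,3.42748484e-02,7.24013930e-03
4.30759477e+01,7.38876125e-02,3.41232683e-02,6.77772929e-03
4.45724378e+01,6.64651269e-02,3.39683396e-02,6.34399064e-03
4.61209171e+01,5.97882777e-02,3.38100432e-02,5.93724455e-03
4.77231917e+01,5.37821610e-02,3.36483629e-02,5.55589964e-03
4.93811305e+01,4.83793972e-02,3.34832859e-02,5.19844846e-03
5.10966673e+01,4.35193758e-02,3.33148025e-02,4.86346417e-03
5.28718032e+01,3.91475748e-02,3.31429070e-02,4.54959716e-03
5.47086085e+01,3.52149493e-02,3.29675969e-02,4.25557174e-03
5.66092258e+01,3.16773813e-02,3.27888739e-02,3.98018288e-03
5.85758720e+01,2.84951847e-02,3.26067434e-02,3.72229300e-03
6.06108409e+01,2.56326603e-02,3.24212151e-02,3.48082885e-03
6.27165061e+01,2.30576948e-02,3.22323028e-02,3.25477848e-03
6.48953237e+01,2.07414012e-02,3.20400245e-02,3.04318820e-03
6.71498350e+01,1.86577941e-02,3.18444027e-02,2.84515975e-03
6.94826697e+01,1.67834988e-02,3.16454645e-02,2.65984746e-03
7.18965488e+01,1.50974884e-02,3.14432412e-02,2.48645559e-03
7.43942878e+01,1.35808487e-02,3.12377691e-02,2.32423565e-03
7.69788001e+01,1.22165651e-02,3.10290889e-02,2.17248397e-03
7.96531002e+01,1.09893327e-02,3.08172459e-02,2.03053920e-03
8.24203076e+01,9.88538356e-03,3.06022904e-02,1.89778008e-03
8.52836497e+01,8.89233325e-03,3.03842770e-02,1.77362315e-03
8.82464665e+01,7.99904122e-03,3.01632652e-02,1.65752068e-03
9.13122136e+01,7.19548611e-03,2.99393190e-02,1.54895862e-03
9.44844672e+01,6.47265329e-03,2.97125068e-02,1.44745469e-03
9.77669271e+01,5.82243366e-03,2.94829018e-02,1.35255653e-03
1.01163422e+02,5.23753278e-03,2.92505811e-02,1.26383997e-03
1.04677914e+02,4.71138895e-03,2.90156263e-02,1.18090737e-03
1.08314502e+02,4.23809964e-03,2.87781230e-02,1.10338603e-03
1.12077427e+02,3.81235529e-03,2.85381607e-02,1.03092674e-03
1.15971079e+02,3.42937970e-03,2.82958326e-02,9.63202317e-04
1.20000000e+02,3.08487647e-03,2.80512355e-02,8.99906324e-04
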