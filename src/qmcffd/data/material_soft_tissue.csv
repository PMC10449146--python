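energy_keV,mu_pe_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.60000000e+01,1.17161070e-01,2.20023047e-02,1.11966348e-02
1.65558518e+01,1.05391488e-01,2.19589813e-02,1.05352802e-02
1.71310142e+01,9.48042355e-02,2.19143907e-02,9.90981365e-03
1.77261583e+01,8.52805407e-02,2.18685037e-02,9.31855887e-03
1.83419781e+01,7.67135622e-02,2.18212909e-02,8.75989826e-03
1.89791919e+01,6.90071918e-02,2.17727226e-02,8.23227227e-03
1.96385430e+01,6.20749759e-02,2.17227694e-02,7.73417846e-03
2.03208004e+01,5.58391456e-02,2.16714013e-02,7.26417035e-03
2.10267600e+01,5.02297445e-02,2.16185888e-02,6.82085627e-03
2.17572451e+01,4.51838438e-02,2.15643022e-02,6.40289822e-03
2.25131078e+01,4.06448363e-02,2.15085119e-02,6.00901063e-03
2.32952297e+01,3.65618013e-02,2.14511885e-02,5.63795922e-03
2.41045232e+01,3.28889333e-02,2.13923026e-02,5.28855984e-03
2.49419320e+01,2.95850286e-02,2.13318253e-02,4.95967727e-03
2.58084331e+01,2.66130223e-02,2.12697280e-02,4.65022414e-03
2.67050371e+01,2.39395732e-02,2.12059824e-02,4.35915970e-03
2.76327897e+01,2.15346892e-02,2.11405605e-02,4.08548874e-03
2.85927732e+01,1.93713912e-02,2.10734351e-02,3.82826039e-03
2.95861071e+01,1.74254105e-02,2.10045794e-02,3.58656697e-03
3.06139503e+01,1.56749160e-02,2.09339674e-02,3.35954277e-03
3.16775014e+01,1.41002699e-02,2.08615737e-02,3.14636284e-03
3.27780012e+01,1.26838072e-02,2.07873738e-02,2.94624182e-03
3.39167330e+01,1.14096372e-02,2.07113442e-02,2.75843263e-03
3.50950253e+01,1.02634658e-02,2.06334623e-02,2.58222525e-03
3.63142523e+01,9.23243473e-03,2.05537066e-02,2.41694543e-03
3.75758362e+01,8.30497732e-03,2.04720567e-02,2.26195346e-03
3.88812484e+01,7.47068897e-03,2.03884936e-02,2.11664282e-03
4.02320115e+01,6.72021025e-03,2.03029995e-02,1.98043897e-03
4.16297012e+01,6.04512193e-03,2.02155583e-02,1.85279802e-03
4.30759477e+01,5.43785058e-03,2.01261552e-02,1.73320552e-03
4.45724378e+01,4.89158354e-03,2.00347771e-02,1.62117514e-03
4.61209171e+01,4.40019253e-03,1.99414128e-02,1.51624752e-03
4.77231917e+01,3.95816491e-03,1.98460525e-02,1.41798896e-03
4.93811305e+01,3.56054181e-03,1.97486889e-02,1.32599033e-03
5.10966673e+01,3.20286250e-03,1.96493162e-02,1.23986584e-03
5.28718032e+01,2.88111437e-03,1.95479309e-02,1.15925191e-03
5.47086085e+01,2.59168792e-03,1.94445317e-02,1.08380611e-03
5.66092258e+01,2.33133621e-03,1.93391196e-02,1.01320608e-03
5.85758720e+01,2.09713850e-03,1.92316977e-02,9.47148450e-04
6.06108409e+01,1.88646746e-03,1.91222717e-02,8.85347927e-04
6.27165061e+01,1.69695968e-03,1.90108498e-02,8.27536273e-04
6.48953237e+01,1.52648917e-03,1.88974427e-02,7.73461408e-04
6.71498350e+01,1.37314352e-03,1.87820635e-02,7.22886527e-04
6.94826697e+01,1.23520243e-03,1.86647283e-02,6.75589250e-04
7.18965488e+01,1.11111841e-03,1.85454555e-02,6.31360816e-04
7.43942878e+01,9.99499421e-04,1.84242665e-02,5.90005311e-04
7.69788001e+01,8.99093280e-04,1.83011854e-02,5.51338932e-04
7.96531002e+01,8.08773581e-04,1.81762389e-02,5.15189285e-04
8.24203076e+01,7.27527077e-04,1.80494565e-02,4.81394725e-04
8.52836497e+01,6.54442306e-04,1.79208706e-02,4.49803718e-04
8.82464665e+01,5.88699370e-04,1.77905162e-02,4.20274243e-04
9.13122136e+01,5.29560734e-04,1.76584311e-02,3.92673229e-04
9.44844672e+01,4.76362955e-04,1.75246556e-02,3.66876008e-04
9.77669271e+01,4.28509234e-04,1.73892328e-02,3.42765814e-04
1.01163422e+02,3.85462728e-04,1.72522084e-02,3.20233302e-04
1.04677914e+02,3.46740519e-04,1.71136303e-02,2.99176087e-04
1.08314502e+02,3.11908205e-04,1.69735491e-02,2.79498324e-04
1.12077427e+02,2.80575021e-04,1.68320176e-02,2.61110301e-04
1.15971079e+02,2.52389457e-04,1.66890907e-02,2.43928056e-04
1.20000000e+02,2.27035314e-04,1.65448255e-02,2.27873022e-04
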