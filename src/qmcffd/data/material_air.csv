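energy_keV,mu_pe_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.60000000e+01,1.28973099e-04,2.27023132e-05,1.29276181e-05
1.65558518e+01,1.16016922e-04,2.26576115e-05,1.21625961e-05
1.71310142e+01,1.04362277e-04,2.26116022e-05,1.14392016e-05
1.77261583e+01,9.38784154e-05,2.25642553e-05,1.07554836e-05
1.83419781e+01,8.44477252e-05,2.25155404e-05,1.01095596e-05
1.89791919e+01,7.59644084e-05,2.24654269e-05,9.49961504e-06
1.96385430e+01,6.83332953e-05,2.24138844e-05,8.92390158e-06
2.03208004e+01,6.14687766e-05,2.23608821e-05,8.38073632e-06
2.10267600e+01,5.52938429e-05,2.23063893e-05,7.86850027e-06
2.17572451e+01,4.97392210e-05,2.22503756e-05,7.38563704e-06
2.25131078e+01,4.47425966e-05,2.21928103e-05,6.93065149e-06
2.32952297e+01,4.02479152e-05,2.21336631e-05,6.50210839e-06
2.41045232e+01,3.62047534e-05,2.20729037e-05,6.09863108e-06
2.49419320e+01,3.25677532e-05,2.20105024e-05,5.71890015e-06
2.58084331e+01,2.92961131e-05,2.19464294e-05,5.36165209e-06
2.67050371e+01,2.63531302e-05,2.18806557e-05,5.02567794e-06
2.76327897e+01,2.37057889e-05,2.18131524e-05,4.70982199e-06
2.85927732e+01,2.13243901e-05,2.17438914e-05,4.41298035e-06
2.95861071e+01,1.91822180e-05,2.16728450e-05,4.13409961e-06
3.06139503e+01,1.72552409e-05,2.15999865e-05,3.87217541e-06
3.16775014e+01,1.55218411e-05,2.15252895e-05,3.62625101e-06
3.27780012e+01,1.39625724e-05,2.14487290e-05,3.39541585e-06
3.39167330e+01,1.25599422e-05,2.13702805e-05,3.17880404e-06
3.50950253e+01,1.12982153e-05,2.12899208e-05,2.97559293e-06
3.63142523e+01,1.01632370e-05,2.12076276e-05,2.78500157e-06
3.75758362e+01,9.14227448e-06,2.11233800e-05,2.60628918e-06
3.88812484e+01,8.22387425e-06,2.10371583e-05,2.43875369e-06
4.02320115e+01,7.39773322e-06,2.09489442e-05,2.28173021e-06
4.16297012e+01,6.65458337e-06,2.08587211e-05,2.13458951e-06
4.30759477e+01,5.98608770e-06,2.07664736e-05,1.99673655e-06
4.45724378e+01,5.38474672e-06,2.06721883e-05,1.86760899e-06
4.61209171e+01,4.84381430e-06,2.05758535e-05,1.74667577e-06
4.77231917e+01,4.35722202e-06,2.04774594e-05,1.63343567e-06
4.93811305e+01,3.91951106e-06,2.03769981e-05,1.52741589e-06
5.10966673e+01,3.52577098e-06,2.02744638e-05,1.42817076e-06
5.28718032e+01,3.17158463e-06,2.01698529e-05,1.33528034e-06
5.47086085e+01,2.85297857e-06,2.00631641e-05,1.24834918e-06
5.66092258e+01,2.56637853e-06,1.99543982e-05,1.16700505e-06
5.85758720e+01,2.30856931e-06,1.98435587e-05,1.09089777e-06
6.06108409e+01,2.07665869e-06,1.97306513e-05,1.01969803e-06
6.27165061e+01,1.86804498e-06,1.96156845e-05,9.53096272e-07
6.48953237e+01,1.68038785e-06,1.94986693e-05,8.90801617e-07
6.71498350e+01,1.51158209e-06,1.93796193e-05,8.32540856e-07
6.94826697e+01,1.35973395e-06,1.92585510e-05,7.78057452e-07
7.18965488e+01,1.22313994e-06,1.91354835e-05,7.27110609e-07
7.43942878e+01,1.10026767e-06,1.90104389e-05,6.79474374e-07
7.69788001e+01,9.89738712e-07,1.88834419e-05,6.34936782e-07
7.96531002e+01,8.90313097e-07,1.87545202e-05,5.93299049e-07
8.24203076e+01,8.00875424e-07,1.86237042e-05,5.54374799e-07
8.52836497e+01,7.20422340e-07,1.84910273e-05,5.17989331e-07
8.82464665e+01,6.48051285e-07,1.83565257e-05,4.83978925e-07
9.13122136e+01,5.82950368e-07,1.82202382e-05,4.52190187e-07
9.44844672e+01,5.24389257e-07,1.80822066e-05,4.22479424e-07
9.77669271e+01,4.71710986e-07,1.79424754e-05,3.94712058e-07
1.01163422e+02,4.24324585e-07,1.78010914e-05,3.68762070e-07
1.04677914e+02,3.81698453e-07,1.76581045e-05,3.44511473e-07
1.08314502e+02,3.43354391e-07,1.75135666e-05,3.21849822e-07
1.12077427e+02,3.08862235e-07,1.73675322e-05,3.00673740e-07
1.15971079e+02,2.77835038e-07,1.72200580e-05,2.80886486e-07
1.20000000e+02,2.49924723e-07,1.70712030e-05,2.62397537e-07
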