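energy_keV,mu_pe_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.60000000e+01,1.68236333e+00,4.90796305e-02,6.81118735e-02
1.65558518e+01,1.51335912e+00,4.89829908e-02,6.41948988e-02
1.71310142e+01,1.36133247e+00,4.88835244e-02,6.04818631e-02
1.77261583e+01,1.22457787e+00,4.87811662e-02,5.69638547e-02
1.83419781e+01,1.10156116e+00,4.86758504e-02,5.36322192e-02
1.89791919e+01,9.90902257e-01,4.85675112e-02,5.04785688e-02
1.96385430e+01,8.91359757e-01,4.84560825e-02,4.74947873e-02
2.03208004e+01,8.01816940e-01,4.83414980e-02,4.46730306e-02
2.10267600e+01,7.21269275e-01,4.82236913e-02,4.20057254e-02
2.17572451e+01,6.48813140e-01,4.81025965e-02,3.94855658e-02
2.25131078e+01,5.83635690e-01,4.79781473e-02,3.71055095e-02
2.32952297e+01,5.25005734e-01,4.78502782e-02,3.48587720e-02
2.41045232e+01,4.72265533e-01,4.77189240e-02,3.27388218e-02
2.49419320e+01,4.24823425e-01,4.75840199e-02,3.07393748e-02
2.58084331e+01,3.82147182e-01,4.74455020e-02,2.88543888e-02
2.67050371e+01,3.43758041e-01,4.73033072e-02,2.70780579e-02
2.76327897e+01,3.09225336e-01,4.71573733e-02,2.54048074e-02
2.85927732e+01,2.78161664e-01,4.70076394e-02,2.38292886e-02
2.95861071e+01,2.50218537e-01,4.68540459e-02,2.23463734e-02
3.06139503e+01,2.25082477e-01,4.66965345e-02,2.09511495e-02
3.16775014e+01,2.02471495e-01,4.65350489e-02,1.96389152e-02
3.27780012e+01,1.82131932e-01,4.63695344e-02,1.84051740e-02
3.39167330e+01,1.63835609e-01,4.61999383e-02,1.72456301e-02
3.50950253e+01,1.47377269e-01,4.60262104e-02,1.61561826e-02
3.63142523e+01,1.32572275e-01,4.58483025e-02,1.51329202e-02
3.75758362e+01,1.19254538e-01,4.56661695e-02,1.41721162e-02
3.88812484e+01,1.07274653e-01,4.54797687e-02,1.32702226e-02
4.02320115e+01,9.64982247e-02,4.52890607e-02,1.24238648e-02
4.16297012e+01,8.68043578e-02,4.50940092e-02,1.16298357e-02
4.30759477e+01,7.80843021e-02,4.48945814e-02,1.08850902e-02
4.45724378e+01,7.02402321e-02,4.46907481e-02,1.01867391e-02
4.61209171e+01,6.31841493e-02,4.44824841e-02,9.53204383e-03
4.77231917e+01,5.68368954e-02,4.42697680e-02,8.91841019e-03
4.93811305e+01,5.11272639e-02,4.40525829e-02,8.34338277e-03
5.10966673e+01,4.59912017e-02,4.38309163e-02,7.80463923e-03
5.28718032e+01,4.13710899e-02,4.36047604e-02,7.29998458e-03
5.47086085e+01,3.72150980e-02,4.33741121e-02,6.82734559e-03
5.66092258e+01,3.34766022e-02,4.31389736e-02,6.38476530e-03
5.85758720e+01,3.01136623e-02,4.28993520e-02,5.97039760e-03
6.06108409e+01,2.70885514e-02,4.26552601e-02,5.58250199e-03
6.27165061e+01,2.43673323e-02,4.24067159e-02,5.21943845e-03
6.48953237e+01,2.19194772e-02,4.21537432e-02,4.87966239e-03
6.71498350e+01,1.97175248e-02,4.18963717e-02,4.56171990e-03
6.94826697e+01,1.77367727e-02,4.16346368e-02,4.26424301e-03
7.18965488e+01,1.59549999e-02,4.13685800e-02,3.98594523e-03
7.43942878e+01,1.43522176e-02,4.10982488e-02,3.72561716e-03
7.69788001e+01,1.29104451e-02,4.08236968e-02,3.48212235e-03
7.96531002e+01,1.16135079e-02,4.05449837e-02,3.25439332e-03
8.24203076e+01,1.04468564e-02,4.02621755e-02,3.04142769e-03
8.52836497e+01,9.39740251e-03,3.99753443e-02,2.84228453e-03
8.82464665e+01,8.45337303e-03,3.96845682e-02,2.65608090e-03
9.13122136e+01,7.60417738e-03,3.93899313e-02,2.48198849e-03
9.44844672e+01,6.84028888e-03,3.90915239e-02,2.31923048e-03
9.77669271e+01,6.15313790e-03,3.87894419e-02,2.16707851e-03
1.01163422e+02,5.53501565e-03,3.84837871e-02,2.02484983e-03
1.04677914e+02,4.97898775e-03,3.81746668e-02,1.89190461e-03
1.08314502e+02,4.47881643e-03,3.78621934e-02,1.76764333e-03
1.12077427e+02,4.02889053e-03,3.75464849e-02,1.65150440e-03
1.15971079e+02,3.62416258e-03,3.72276638e-02,1.54296185e-03
1.20000000e+02,3.26009216e-03,3.69058575e-02,1.44152313e-03
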