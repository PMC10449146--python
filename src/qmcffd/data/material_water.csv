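energy_keV,mu_pe_per_mm,mu_compton_per_mm,mu_rayleigh_per_mm
1.60000000e+01,1.04839620e-01,2.09084994e-02,1.08488456e-02
1.65558518e+01,9.43078064e-02,2.08673297e-02,1.02080116e-02
1.71310142e+01,8.48339811e-02,2.08249559e-02,9.60194666e-03
1.77261583e+01,7.63118624e-02,2.07813501e-02,9.02902666e-03
1.83419781e+01,6.86458454e-02,2.07364843e-02,8.48768487e-03
1.89791919e+01,6.17499290e-02,2.06903305e-02,7.97641102e-03
1.96385430e+01,5.55467517e-02,2.06428606e-02,7.49375028e-03
2.03208004e+01,4.99667235e-02,2.05940462e-02,7.03830206e-03
2.10267600e+01,4.49472450e-02,2.05438592e-02,6.60871890e-03
2.17572451e+01,4.04320053e-02,2.04922714e-02,6.20370522e-03
2.25131078e+01,3.63703505e-02,2.04392546e-02,5.82201614e-03
2.32952297e+01,3.27167150e-02,2.03847809e-02,5.46245638e-03
2.41045232e+01,2.94301107e-02,2.03288224e-02,5.12387904e-03
2.49419320e+01,2.64736669e-02,2.02713517e-02,4.80518457e-03
2.58084331e+01,2.38142169e-02,2.02123414e-02,4.50531959e-03
2.67050371e+01,2.14219258e-02,2.01517648e-02,4.22327585e-03
2.76327897e+01,1.92699557e-02,2.00895952e-02,3.95808906e-03
2.85927732e+01,1.73341648e-02,2.00258068e-02,3.70883786e-03
2.95861071e+01,1.55928365e-02,1.99603742e-02,3.47464263e-03
3.06139503e+01,1.40264358e-02,1.98932725e-02,3.25466437e-03
3.16775014e+01,1.26173902e-02,1.98244777e-02,3.04810357e-03
3.27780012e+01,1.13498923e-02,1.97539666e-02,2.85419900e-03
3.39167330e+01,1.02097226e-02,1.96817167e-02,2.67222651e-03
3.50950253e+01,9.18409038e-03,1.96077065e-02,2.50149788e-03
3.63142523e+01,8.26148947e-03,1.95319157e-02,2.34135953e-03
3.75758362e+01,7.43156975e-03,1.94543249e-02,2.19119132e-03
3.88812484e+01,6.68502081e-03,1.93749159e-02,2.05040533e-03
4.02320115e+01,6.01346750e-03,1.92936721e-02,1.91844461e-03
4.16297012e+01,5.40937604e-03,1.92105779e-02,1.79478192e-03
4.30759477e+01,4.86596945e-03,1.91256193e-02,1.67891857e-03
4.45724378e+01,4.37715154e-03,1.90387839e-02,1.57038315e-03
4.61209171e+01,3.93743853e-03,1.89500610e-02,1.46873036e-03
4.77231917e+01,3.54189753e-03,1.88594414e-02,1.37353983e-03
4.93811305e+01,3.18609115e-03,1.87669180e-02,1.28441498e-03
5.10966673e+01,2.86602782e-03,1.86724854e-02,1.20098187e-03
5.28718032e+01,2.57811690e-03,1.85761404e-02,1.12288811e-03
5.47086085e+01,2.31912849e-03,1.84778815e-02,1.04980181e-03
5.66092258e+01,2.08615713e-03,1.83777097e-02,9.81410525e-04
5.85758720e+01,1.87658924e-03,1.82756281e-02,9.17420257e-04
6.06108409e+01,1.68807379e-03,1.81716421e-02,8.57554502e-04
6.27165061e+01,1.51849592e-03,1.80657593e-02,8.01553311e-04
6.48953237e+01,1.36595325e-03,1.79579900e-02,7.49172398e-04
6.71498350e+01,1.22873447e-03,1.78483467e-02,7.00182284e-04
6.94826697e+01,1.10530019e-03,1.77368446e-02,6.54367474e-04
7.18965488e+01,9.94265682e-04,1.76235012e-02,6.11525679e-04
7.43942878e+01,8.94385304e-04,1.75083370e-02,5.71467061e-04
7.69788001e+01,8.04538552e-04,1.73913746e-02,5.34013520e-04
7.96531002e+01,7.23717483e-04,1.72726395e-02,4.98998021e-04
8.24203076e+01,6.51015410e-04,1.71521599e-02,4.66263941e-04
8.52836497e+01,5.85616728e-04,1.70299665e-02,4.35664461e-04
8.82464665e+01,5.26787764e-04,1.69060924e-02,4.07061981e-04
9.13122136e+01,4.73868547e-04,1.67805736e-02,3.80327575e-04
9.44844672e+01,4.26265406e-04,1.66534486e-02,3.55340461e-04
9.77669271e+01,3.83444306e-04,1.65247581e-02,3.31987515e-04
1.01163422e+02,3.44924861e-04,1.63945456e-02,3.10162801e-04
1.04677914e+02,3.10274942e-04,1.62628567e-02,2.89767134e-04
1.08314502e+02,2.79105830e-04,1.61297394e-02,2.70707661e-04
1.12077427e+02,2.51067855e-04,1.59952438e-02,2.52897474e-04
1.15971079e+02,2.25846475e-04,1.58594223e-02,2.36255235e-04
1.20000000e+02,2.03158745e-04,1.57223290e-02,2.20704835e-04
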