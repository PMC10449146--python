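energy_keV,weight
1.60000000e+01,1.07475555e-03
1.70000000e+01,2.09568594e-03
1.80000000e+01,3.50424019e-03
1.90000000e+01,5.22598933e-03
2.00000000e+01,7.14778483e-03
2.10000000e+01,9.14898717e-03
2.20000000e+01,1.11229938e-02
2.30000000e+01,1.29875757e-02
2.40000000e+01,1.46868368e-02
2.50000000e+01,1.61883831e-02
2.60000000e+01,1.74785075e-02
2.70000000e+01,1.85571175e-02
2.80000000e+01,1.94332660e-02
2.90000000e+01,2.01215911e-02
3.00000000e+01,2.06396730e-02
3.10000000e+01,2.10061798e-02
3.20000000e+01,2.12396394e-02
3.30000000e+01,2.13576753e-02
3.40000000e+01,2.13765750e-02
3.50000000e+01,2.13110859e-02
3.60000000e+01,2.11743600e-02
3.70000000e+01,2.09779928e-02
3.80000000e+01,2.07321170e-02
3.90000000e+01,2.04455252e-02
4.00000000e+01,2.01258035e-02
4.10000000e+01,1.97794669e-02
4.20000000e+01,1.94120875e-02
4.30000000e+01,1.90284145e-02
4.40000000e+01,1.86324828e-02
4.50000000e+01,1.82277093e-02
4.60000000e+01,1.78169795e-02
4.70000000e+01,1.74027214e-02
4.80000000e+01,1.69869717e-02
4.90000000e+01,1.65714321e-02
5.00000000e+01,1.61575178e-02
5.10000000e+01,1.57464000e-02
5.20000000e+01,1.53390416e-02
5.30000000e+01,1.49362287e-02
5.40000000e+01,1.45385966e-02
5.50000000e+01,1.41466525e-02
5.60000000e+01,1.37607955e-02
5.70000000e+01,1.33813323e-02
5.80000000e+01,1.30084922e-02
5.90000000e+01,1.26424388e-02
6.00000000e+01,1.22832803e-02
6.10000000e+01,1.19310784e-02
6.20000000e+01,1.15858560e-02
6.30000000e+01,1.12476035e-02
6.40000000e+01,1.09162841e-02
6.50000000e+01,1.05918390e-02
6.60000000e+01,1.02741907e-02
6.70000000e+01,9.96324726e-03
6.80000000e+01,9.65890427e-03
6.90000000e+01,9.36104804e-03
7.00000000e+01,9.06955736e-03
7.10000000e+01,8.78430534e-03
7.20000000e+01,8.50516097e-03
7.30000000e+01,8.23199034e-03
7.40000000e+01,7.96465773e-03
7.50000000e+01,7.70302653e-03
7.60000000e+01,7.44695999e-03
7.70000000e+01,7.19632187e-03
7.80000000e+01,6.95097693e-03
7.90000000e+01,6.71079141e-03
8.00000000e+01,6.47563334e-03
8.10000000e+01,6.24537288e-03
8.20000000e+01,6.01988250e-03
8.30000000e+01,5.79903721e-03
8.40000000e+01,5.58271465e-03
8.50000000e+01,5.37079524e-03
8.60000000e+01,5.16316224e-03
8.70000000e+01,4.95970177e-03
8.80000000e+01,4.76030288e-03
8.90000000e+01,4.56485755e-03
9.00000000e+01,4.37326066e-03
9.10000000e+01,4.18540999e-03
9.20000000e+01,4.00120618e-03
9.30000000e+01,3.82055272e-03
9.40000000e+01,3.64335586e-03
9.50000000e+01,3.46952459e-03
9.60000000e+01,3.29897059e-03
9.70000000e+01,3.13160814e-03
9.80000000e+01,2.96735409e-03
9.90000000e+01,2.80612778e-03
1.00000000e+02,2.64785098e-03
1.01000000e+02,2.49244781e-03
1.02000000e+02,2.33984471e-03
1.03000000e+02,2.18997032e-03
1.04000000e+02,2.04275549e-03
1.05000000e+02,1.89813312e-03
1.06000000e+02,1.75603819e-03
1.07000000e+02,1.61640763e-03
1.08000000e+02,1.47918029e-03
1.09000000e+02,1.34429686e-03
1.10000000e+02,1.21169984e-03
1.11000000e+02,1.08133345e-03
1.12000000e+02,9.53143592e-04
1.13000000e+02,8.27077796e-04
1.14000000e+02,7.03085156e-04
1.15000000e+02,5.81116284e-04
1.16000000e+02,4.61123264e-04
1.17000000e+02,3.43059594e-04
1.18000000e+02,2.26880147e-04
1.19000000e+02,1.12541122e-04
1.20000000e+02,0.00000000e+00
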