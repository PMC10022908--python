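# C (Z=6) partial mass attenuation coefficients, cm^2/g
# generated 2026-09-29 by mammomc.oracles.generate_xsec_fixtures
# photoelectric: Cromer-Liberman f''; coherent: Thomson x IT92 F^2;
# incoherent: Klein-Nishina x S, S(x)=Z(1-(F/Z)^2)
# grid: 81 log-spaced points, 1-100 keV
energy_keV,mu_pe,mu_incoh,mu_coh
1.00000000e+00,2.07252489e+03,2.02021091e-02,1.07889326e+00
1.05925373e+00,1.76493942e+03,2.23694687e-02,1.06577708e+00
1.12201845e+00,1.50184778e+03,2.47354186e-02,1.05145158e+00
1.18850223e+00,1.27581582e+03,2.73104458e-02,1.03585143e+00
1.25892541e+00,1.08285488e+03,3.01039114e-02,1.01891784e+00
1.33352143e+00,9.18503453e+02,3.31235749e-02,1.00060141e+00
1.41253754e+00,7.78609113e+02,3.63751171e-02,9.80865036e-01
1.49623566e+00,6.59608474e+02,3.98617063e-02,9.59686545e-01
1.58489319e+00,5.58445671e+02,4.35834467e-02,9.37062027e-01
1.67880402e+00,4.72501835e+02,4.75369225e-02,9.13008637e-01
1.77827941e+00,3.99534098e+02,5.17148123e-02,8.87566974e-01
1.88364909e+00,3.37622901e+02,5.61055504e-02,8.60803181e-01
1.99526231e+00,2.85126486e+02,6.06931689e-02,8.32809974e-01
2.11348904e+00,2.40641633e+02,6.54572505e-02,8.03707005e-01
2.23872114e+00,2.02969806e+02,7.03731943e-02,7.73639343e-01
2.37137371e+00,1.71087983e+02,7.54125423e-02,7.42775572e-01
2.51188643e+00,1.44123534e+02,8.05436096e-02,7.11304062e-01
2.66072506e+00,1.21332618e+02,8.57322872e-02,6.79428175e-01
2.81838293e+00,1.02081593e+02,9.09429534e-02,6.47360788e-01
2.98538262e+00,8.58310550e+01,9.61394806e-02,6.15318231e-01
3.16227766e+00,7.20890056e+01,1.01286253e-01,5.83514125e-01
3.34965439e+00,6.05124986e+01,1.06349097e-01,5.52153720e-01
3.54813389e+00,5.07683388e+01,1.11296189e-01,5.21428362e-01
3.75837404e+00,4.25708760e+01,1.16098695e-01,4.91511550e-01
3.98107171e+00,3.56782828e+01,1.20731398e-01,4.62555061e-01
4.21696503e+00,2.98859439e+01,1.25173067e-01,4.34686600e-01
4.46683592e+00,2.50208264e+01,1.29406731e-01,4.08008061e-01
4.73151259e+00,2.09366852e+01,1.33419820e-01,3.82594532e-01
5.01187234e+00,1.75099844e+01,1.37204125e-01,3.58494414e-01
5.30884444e+00,1.46364289e+01,1.40755673e-01,3.35730072e-01
5.62341325e+00,1.22213142e+01,1.44074399e-01,3.14299710e-01
5.95662144e+00,1.02003949e+01,1.47163724e-01,2.94179837e-01
6.30957344e+00,8.51043004e+00,1.50029982e-01,2.75328698e-01
6.68343918e+00,7.09776191e+00,1.52681805e-01,2.57689949e-01
7.07945784e+00,5.91734248e+00,1.55129478e-01,2.41196615e-01
7.49894209e+00,4.93136675e+00,1.57384337e-01,2.25774706e-01
7.94328235e+00,4.10812056e+00,1.59458257e-01,2.11346413e-01
8.41395142e+00,3.42100971e+00,1.61363223e-01,1.97832729e-01
8.91250938e+00,2.84762336e+00,1.63111000e-01,1.85155496e-01
9.44060876e+00,2.36573226e+00,1.64712824e-01,1.73239354e-01
1.00000000e+01,1.96502711e+00,1.66179176e-01,1.62013199e-01
1.05925373e+01,1.63189197e+00,1.67519527e-01,1.51411804e-01
1.12201845e+01,1.35498398e+00,1.68742174e-01,1.41376969e-01
1.18850223e+01,1.12485568e+00,1.69854104e-01,1.31858439e-01
1.25892541e+01,9.33639765e-01,1.70860945e-01,1.22814333e-01
1.33352143e+01,7.74785995e-01,1.71766978e-01,1.14211192e-01
1.41253754e+01,6.42841739e-01,1.72575205e-01,1.06023627e-01
1.49623566e+01,5.33268902e-01,1.73287475e-01,9.82335693e-02
1.58489319e+01,4.42291237e-01,1.73904637e-01,9.08296544e-02
1.67880402e+01,3.66767040e-01,1.74426731e-01,8.38057489e-02
1.77827941e+01,3.04083010e-01,1.74853384e-01,7.71597716e-02
1.88364909e+01,2.52065789e-01,1.75183503e-01,7.08920963e-02
1.99526231e+01,2.08908233e-01,1.75416220e-01,6.50039487e-02
2.11348904e+01,1.73107988e-01,1.75550743e-01,5.94957510e-02
2.23872114e+01,1.43416320e-01,1.75586641e-01,5.43657248e-02
2.37137371e+01,1.18795492e-01,1.75523997e-01,4.96088177e-02
2.51188643e+01,9.83832738e-02,1.75363476e-01,4.52161529e-02
2.66072506e+01,8.14633970e-02,1.75106323e-01,4.11749762e-02
2.81838293e+01,6.73057264e-02,1.74754279e-01,3.74691199e-02
2.98538262e+01,5.56038731e-02,1.74309467e-01,3.40797921e-02
3.16227766e+01,4.59389148e-02,1.73774247e-01,3.09865490e-02
3.34965439e+01,3.79558763e-02,1.73151095e-01,2.81681929e-02
3.54813389e+01,3.13617189e-02,1.72442503e-01,2.56035402e-02
3.75837404e+01,2.59145209e-02,1.71650916e-01,2.32719361e-02
3.98107171e+01,2.14145497e-02,1.70778702e-01,2.11535840e-02
4.21696503e+01,1.76968958e-02,1.69828134e-01,1.92297658e-02
4.46683592e+01,1.46253940e-02,1.68801386e-01,1.74829726e-02
4.73151259e+01,1.20876073e-02,1.67700532e-01,1.58970179e-02
5.01187234e+01,9.99068690e-03,1.66527549e-01,1.44571160e-02
5.30884444e+01,8.25795573e-03,1.65284332e-01,1.31498787e-02
5.62341325e+01,6.82608833e-03,1.63972712e-01,1.19632702e-02
5.95662144e+01,5.64278323e-03,1.62594487e-01,1.08864759e-02
6.30957344e+01,4.66484161e-03,1.61151456e-01,9.90975164e-03
6.68343918e+01,3.85658113e-03,1.59645445e-01,9.02428904e-03
7.07945784e+01,3.18852656e-03,1.58078328e-01,8.22210516e-03
7.49894209e+01,2.63632879e-03,1.56452047e-01,7.49598266e-03
7.94328235e+01,2.17987223e-03,1.54830566e-01,6.83942643e-03
8.41395142e+01,1.80253791e-03,1.53091272e-01,6.24661380e-03
8.91250938e+01,1.49059498e-03,1.51297979e-01,5.71232100e-03
9.44060876e+01,1.23269818e-03,1.49453121e-01,5.23182713e-03
1.00000000e+02,1.01947289e-03,1.47559285e-01,4.80081176e-03
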