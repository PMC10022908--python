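# H (Z=1) partial mass attenuation coefficients, cm^2/g
# generated 2026-09-29 by mammomc.oracles.generate_xsec_fixtures
# photoelectric: Cromer-Liberman f''; coherent: Thomson x IT92 F^2;
# incoherent: Klein-Nishina x S, S(x)=Z(1-(F/Z)^2)
# grid: 81 log-spaced points, 1-100 keV
energy_keV,mu_pe,mu_incoh,mu_coh
1.00000000e+00,6.81522229e+00,3.85785989e-02,3.58653374e-01
1.05925373e+00,5.62291529e+00,4.28097510e-02,3.54385892e-01
1.12201845e+00,4.63812998e+00,4.74482689e-02,3.49705114e-01
1.18850223e+00,3.82495530e+00,5.25203231e-02,3.44584019e-01
1.25892541e+00,3.15365418e+00,5.80507606e-02,3.38996816e-01
1.33352143e+00,2.59960985e+00,6.40622853e-02,3.32919771e-01
1.41253754e+00,2.14245049e+00,7.05745664e-02,3.26332095e-01
1.49623566e+00,1.76532228e+00,7.76031458e-02,3.19217050e-01
1.58489319e+00,1.45428607e+00,8.51583442e-02,3.11563046e-01
1.67880402e+00,1.19781658e+00,9.32440177e-02,3.03364908e-01
1.77827941e+00,9.86387159e-01,1.01856397e-01,2.94625051e-01
1.88364909e+00,8.12125309e-01,1.10982984e-01,2.85354617e-01
1.99526231e+00,6.68527273e-01,1.20601490e-01,2.75574564e-01
2.11348904e+00,5.50221467e-01,1.30679140e-01,2.65316400e-01
2.23872114e+00,4.52772542e-01,1.41172286e-01,2.54622609e-01
2.37137371e+00,3.72519131e-01,1.52026284e-01,2.43546812e-01
2.51188643e+00,3.06439536e-01,1.63176131e-01,2.32153167e-01
2.66072506e+00,2.52040572e-01,1.74547389e-01,2.20515480e-01
2.81838293e+00,2.07265615e-01,1.86057844e-01,2.08715565e-01
2.98538262e+00,1.70418552e-01,1.97619690e-01,1.96841073e-01
3.16227766e+00,1.40100899e-01,2.09142017e-01,1.84982994e-01
3.34965439e+00,1.15159828e-01,2.20533705e-01,1.73232748e-01
3.54813389e+00,9.46452229e-02,2.31706558e-01,1.61679007e-01
3.75837404e+00,7.77741952e-02,2.42578064e-01,1.50404878e-01
3.98107171e+00,6.39017855e-02,2.53074143e-01,1.39485096e-01
4.21696503e+00,5.24967684e-02,2.63131164e-01,1.28983928e-01
4.46683592e+00,4.31216825e-02,2.72697425e-01,1.18953618e-01
4.73151259e+00,3.54163486e-02,2.81733845e-01,1.09433633e-01
5.01187234e+00,2.90842727e-02,2.90213878e-01,1.00450685e-01
5.30884444e+00,2.38814294e-02,2.98122835e-01,9.20193774e-02
5.62341325e+00,1.96070129e-02,3.05456711e-01,8.41433396e-02
5.95662144e+00,1.60958104e-02,3.12220646e-01,7.68167639e-02
6.30957344e+00,1.32119165e-02,3.18427298e-01,7.00260336e-02
6.68343918e+00,1.08435524e-02,3.24095130e-01,6.37514433e-02
7.07945784e+00,8.89879792e-03,3.29246809e-01,5.79688329e-02
7.49894209e+00,7.30207487e-03,3.33907676e-01,5.26511425e-02
7.94328235e+00,5.99125144e-03,3.38104396e-01,4.77698033e-02
8.41395142e+00,4.91525737e-03,3.41863859e-01,4.32958789e-02
8.91250938e+00,4.03212077e-03,3.45212332e-01,3.92009510e-02
9.44060876e+00,3.30735205e-03,3.48174887e-01,3.54577230e-02
1.00000000e+01,2.71261396e-03,3.50775127e-01,3.20403223e-02
1.05925373e+01,2.22462726e-03,3.53035075e-01,2.89244193e-02
1.12201845e+01,1.82427042e-03,3.54975230e-01,2.60871800e-02
1.18850223e+01,1.49583898e-03,3.56614679e-01,2.35071542e-02
1.25892541e+01,1.22643660e-03,3.57971205e-01,2.11641667e-02
1.33352143e+01,1.00547416e-03,3.59061377e-01,1.90392253e-02
1.41253754e+01,8.24258024e-04,3.59900602e-01,1.71144709e-02
1.49623566e+01,6.75651584e-04,3.60503142e-01,1.53731611e-02
1.58489319e+01,5.53797032e-04,3.60882155e-01,1.37996079e-02
1.67880402e+01,4.53886744e-04,3.61049709e-01,1.23792503e-02
1.77827941e+01,3.71975423e-04,3.61016820e-01,1.10985145e-02
1.88364909e+01,3.04825762e-04,3.60793497e-01,9.94482982e-03
1.99526231e+01,2.49781657e-04,3.60389335e-01,8.90657297e-03
2.11348904e+01,2.04664084e-04,3.59811794e-01,7.97301968e-03
2.23872114e+01,1.67685568e-04,3.59068526e-01,7.13430337e-03
2.37137371e+01,1.37379971e-04,3.58166098e-01,6.38136949e-03
2.51188643e+01,1.12544829e-04,3.57110348e-01,5.70592837e-03
2.66072506e+01,9.21940186e-05,3.55906444e-01,5.10041051e-03
2.81838293e+01,7.55189068e-05,3.54558943e-01,4.55792033e-03
2.98538262e+01,6.18564574e-05,3.53071852e-01,4.07218832e-03
3.16227766e+01,5.06630617e-05,3.51448695e-01,3.63752233e-03
3.34965439e+01,4.14930613e-05,3.49692577e-01,3.24876097e-03
3.54813389e+01,3.39811277e-05,3.47806248e-01,2.90122620e-03
3.75837404e+01,2.78278048e-05,3.45792170e-01,2.59067659e-03
3.98107171e+01,2.27876498e-05,3.43652584e-01,2.31326255e-03
4.21696503e+01,1.86595045e-05,3.41389573e-01,2.06548102e-03
4.46683592e+01,1.52785172e-05,3.39005132e-01,1.84412831e-03
4.73151259e+01,1.25095984e-05,3.36501228e-01,1.64626048e-03
5.01187234e+01,1.02420550e-05,3.33879851e-01,1.46916293e-03
5.30884444e+01,8.38519023e-06,3.31143051e-01,1.31033733e-03
5.62341325e+01,6.86469589e-06,3.28292948e-01,1.16750568e-03
5.95662144e+01,5.61969480e-06,3.25331740e-01,1.03862765e-03
6.30957344e+01,4.60031603e-06,3.22261696e-01,9.21918202e-04
6.68343918e+01,3.76570735e-06,3.19085165e-01,8.15859760e-04
7.07945784e+01,3.08240618e-06,3.15804586e-01,7.19201041e-04
7.49894209e+01,2.52300433e-06,3.12422513e-01,6.30943498e-04
7.94328235e+01,2.06505381e-06,3.08941653e-01,5.50313821e-04
8.41395142e+01,1.69017005e-06,3.05516406e-01,4.76730680e-04
8.91250938e+01,1.38329713e-06,3.01843803e-01,4.09768211e-04
9.44060876e+01,1.13210572e-06,2.98078272e-01,3.49119303e-04
1.00000000e+02,9.26499737e-07,2.94224022e-01,2.94557840e-04
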