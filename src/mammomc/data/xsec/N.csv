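# N (Z=7) partial mass attenuation coefficients, cm^2/g
# generated 2026-09-29 by mammomc.oracles.generate_xsec_fixtures
# photoelectric: Cromer-Liberman f''; coherent: Thomson x IT92 F^2;
# incoherent: Klein-Nishina x S, S(x)=Z(1-(F/Z)^2)
# grid: 81 log-spaced points, 1-100 keV
energy_keV,mu_pe,mu_incoh,mu_coh
1.00000000e+00,3.16927486e+03,1.57244318e-02,1.29080575e+00
1.05925373e+00,2.70802727e+03,1.74425306e-02,1.27867553e+00
1.12201845e+00,2.31213140e+03,1.93319806e-02,1.26532865e+00
1.18850223e+00,1.97259604e+03,2.14051830e-02,1.25067575e+00
1.25892541e+00,1.68162747e+03,2.36743085e-02,1.23462875e+00
1.33352143e+00,1.43247568e+03,2.61510111e-02,1.21710291e+00
1.41253754e+00,1.21929947e+03,2.88460926e-02,1.19801911e+00
1.49623566e+00,1.03704841e+03,3.17690530e-02,1.17730707e+00
1.58489319e+00,8.81359405e+02,3.49276006e-02,1.15490875e+00
1.67880402e+00,7.48045799e+02,3.83271448e-02,1.13078197e+00
1.77827941e+00,6.34380291e+02,4.19702862e-02,1.10490400e+00
1.88364909e+00,5.37649708e+02,4.58561828e-02,1.07727609e+00
1.99526231e+00,4.55383449e+02,4.99800803e-02,1.04792684e+00
2.11348904e+00,3.85463290e+02,5.43329035e-02,1.01691513e+00
2.23872114e+00,3.26074339e+02,5.89008289e-02,9.84333315e-01
2.37137371e+00,2.75662638e+02,6.36651417e-02,9.50308251e-01
2.51188643e+00,2.32898533e+02,6.86023375e-02,9.15000766e-01
2.66072506e+00,1.96645055e+02,7.36843281e-02,8.78604315e-01
2.81838293e+00,1.65930654e+02,7.88790009e-02,8.41341144e-01
2.98538262e+00,1.39925677e+02,8.41511112e-02,8.03456093e-01
3.16227766e+00,1.17837817e+02,8.94632097e-02,7.65210112e-01
3.34965439e+00,9.91773318e+01,9.47769207e-02,7.26871264e-01
3.54813389e+00,8.34278778e+01,1.00054186e-01,6.88705918e-01
3.75837404e+00,7.01424498e+01,1.05258477e-01,6.50970125e-01
3.98107171e+00,5.89415480e+01,1.10355905e-01,6.13901705e-01
4.21696503e+00,4.95031482e+01,1.15316045e-01,5.77714270e-01
4.46683592e+00,4.15541350e+01,1.20112476e-01,5.42593322e-01
4.73151259e+00,3.48631406e+01,1.24722989e-01,5.08694629e-01
5.01187234e+00,2.92340853e+01,1.29129629e-01,4.76143875e-01
5.30884444e+00,2.45009637e+01,1.33318395e-01,4.45038650e-01
5.62341325e+00,2.05233097e+01,1.37278986e-01,4.15450218e-01
5.95662144e+00,1.71823328e+01,1.41004484e-01,3.87425650e-01
6.30957344e+00,1.43776292e+01,1.44491088e-01,3.60989674e-01
6.68343918e+00,1.20243826e+01,1.47737988e-01,3.36145405e-01
7.07945784e+00,1.00509842e+01,1.50747207e-01,3.12875362e-01
7.49894209e+00,8.39700903e+00,1.53523490e-01,2.91142121e-01
7.94328235e+00,7.01072612e+00,1.56074121e-01,2.70889454e-01
8.41395142e+00,5.85082829e+00,1.58408571e-01,2.52044708e-01
8.91250938e+00,4.88066433e+00,1.60538076e-01,2.34521793e-01
9.44060876e+00,4.06390720e+00,1.62475025e-01,2.18225472e-01
1.00000000e+01,3.38305850e+00,1.64232294e-01,2.03056252e-01
1.05925373e+01,2.81563321e+00,1.65822584e-01,1.88915221e-01
1.12201845e+01,2.34284449e+00,1.67257860e-01,1.75708213e-01
1.18850223e+01,1.94899904e+00,1.68548935e-01,1.63349033e-01
1.25892541e+01,1.62098250e+00,1.69705245e-01,1.51761180e-01
1.33352143e+01,1.34786329e+00,1.70734801e-01,1.40878367e-01
1.41253754e+01,1.12050664e+00,1.71644267e-01,1.30644053e-01
1.49623566e+01,9.31288151e-01,1.72439073e-01,1.21010700e-01
1.58489319e+01,7.73846379e-01,1.73123580e-01,1.11938680e-01
1.67880402e+01,6.42874874e-01,1.73701247e-01,1.03395093e-01
1.77827941e+01,5.33948236e-01,1.74174753e-01,9.53528760e-02
1.88364909e+01,4.43376688e-01,1.74546180e-01,8.77896519e-02
1.99526231e+01,3.68084507e-01,1.74817144e-01,8.06866420e-02
2.11348904e+01,3.05508430e-01,1.74989094e-01,7.40273841e-02
2.23872114e+01,2.53512762e-01,1.75063053e-01,6.77968048e-02
2.37137371e+01,2.10318473e-01,1.75040234e-01,6.19801681e-02
2.51188643e+01,1.74443974e-01,1.74921872e-01,5.65622011e-02
2.66072506e+01,1.44655676e-01,1.74709328e-01,5.15267862e-02
2.81838293e+01,1.19724057e-01,1.74404103e-01,4.68567828e-02
2.98538262e+01,9.90752160e-02,1.74007791e-01,4.25344626e-02
3.16227766e+01,8.19853221e-02,1.73521994e-01,3.85422649e-02
3.34965439e+01,6.78413696e-02,1.72948181e-01,3.48640542e-02
3.54813389e+01,5.61358721e-02,1.72287529e-01,3.14866583e-02
3.75837404e+01,4.64487097e-02,1.71540738e-01,2.84017514e-02
3.98107171e+01,3.84320985e-02,1.70707838e-01,2.56079391e-02
4.21696503e+01,3.17981429e-02,1.69787988e-01,2.31130539e-02
4.46683592e+01,2.63085300e-02,1.68779309e-01,2.09364381e-02
4.73151259e+01,2.17659952e-02,1.67678689e-01,1.91116108e-02
5.01187234e+01,1.80072566e-02,1.66481604e-01,1.76890556e-02
5.30884444e+01,1.48971644e-02,1.65181902e-01,1.67396105e-02
5.62341325e+01,1.23238574e-02,1.63771570e-01,1.63583755e-02
5.95662144e+01,1.01947521e-02,1.62240465e-01,1.66694050e-02
6.30957344e+01,8.43322318e-03,1.60575999e-01,1.78312490e-02
6.68343918e+01,6.97585428e-03,1.58762820e-01,2.00432305e-02
7.07945784e+01,5.77016264e-03,1.56782488e-01,2.35524907e-02
7.49894209e+01,4.77271525e-03,1.54613164e-01,2.86616405e-02
7.94328235e+01,3.94756945e-03,1.52229360e-01,3.57366738e-02
8.41395142e+01,3.26498200e-03,1.49601771e-01,4.52149592e-02
8.91250938e+01,2.70034052e-03,1.46697238e-01,5.76125303e-02
9.44060876e+01,2.23327899e-03,1.43539401e-01,7.35301224e-02
1.00000000e+02,1.84694562e-03,1.39965569e-01,9.36569185e-02
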