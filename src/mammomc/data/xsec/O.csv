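# O (Z=8) partial mass attenuation coefficients, cm^2/g
# generated 2026-09-29 by mammomc.oracles.generate_xsec_fixtures
# photoelectric: Cromer-Liberman f''; coherent: Thomson x IT92 F^2;
# incoherent: Klein-Nishina x S, S(x)=Z(1-(F/Z)^2)
# grid: 81 log-spaced points, 1-100 keV
energy_keV,mu_pe,mu_incoh,mu_coh
1.00000000e+00,4.41915356e+03,1.25676702e-02,1.50149443e+00
1.05925373e+00,3.79347855e+03,1.39862529e-02,1.49004869e+00
1.12201845e+00,3.25359592e+03,1.55515287e-02,1.47741289e+00
1.18850223e+00,2.78815439e+03,1.72754515e-02,1.46348882e+00
1.25892541e+00,2.38724520e+03,1.91701429e-02,1.44817658e+00
1.33352143e+00,2.04222712e+03,2.12477382e-02,1.43137583e+00
1.41253754e+00,1.74557153e+03,2.35201620e-02,1.41298752e+00
1.49623566e+00,1.49072546e+03,2.59987983e-02,1.39291653e+00
1.58489319e+00,1.27199062e+03,2.86941494e-02,1.37107441e+00
1.67880402e+00,1.08441669e+03,3.16154611e-02,1.34738239e+00
1.77827941e+00,9.23707224e+02,3.47702465e-02,1.32177516e+00
1.88364909e+00,7.86136914e+02,3.81638155e-02,1.29420474e+00
1.99526231e+00,6.68478708e+02,4.17987920e-02,1.26464439e+00
2.11348904e+00,5.67939863e+02,4.56745775e-02,1.23309292e+00
2.23872114e+00,4.81869256e+02,4.97869282e-02,1.19957826e+00
2.37137371e+00,4.08546930e+02,5.41275417e-02,1.16416081e+00
2.51188643e+00,3.46158335e+02,5.86837286e-02,1.12693626e+00
2.66072506e+00,2.93107941e+02,6.34382902e-02,1.08803666e+00
2.81838293e+00,2.48027687e+02,6.83695036e-02,1.04763074e+00
2.98538262e+00,2.09745365e+02,7.34513300e-02,1.00592233e+00
3.16227766e+00,1.77114299e+02,7.86538296e-02,9.63147187e-01
3.34965439e+00,1.49465549e+02,8.39437692e-02,9.19568211e-01
3.54813389e+00,1.26063733e+02,8.92853965e-02,8.75469315e-01
3.75837404e+00,1.06267769e+02,9.46413842e-02,8.31147866e-01
3.98107171e+00,8.95313412e+01,9.99738138e-02,7.86906781e-01
4.21696503e+00,7.53894431e+01,1.05245271e-01,7.43045666e-01
4.46683592e+00,6.34465053e+01,1.10419812e-01,6.99852941e-01
4.73151259e+00,5.33662170e+01,1.15463969e-01,6.57597640e-01
5.01187234e+00,4.48628129e+01,1.20347569e-01,6.16522612e-01
5.30884444e+00,3.76936149e+01,1.25044389e-01,5.76839053e-01
5.62341325e+00,3.16526541e+01,1.29532712e-01,5.38721791e-01
5.95662144e+00,2.65652179e+01,1.33795554e-01,5.02307235e-01
6.30957344e+00,2.22831921e+01,1.37820765e-01,4.67692316e-01
6.68343918e+00,1.86810838e+01,1.41600810e-01,4.34936064e-01
7.07945784e+00,1.56526277e+01,1.45132395e-01,4.04062524e-01
7.49894209e+00,1.31078917e+01,1.48415910e-01,3.75065087e-01
7.94328235e+00,1.09708110e+01,1.51454765e-01,3.47911898e-01
8.41395142e+00,9.17708627e+00,1.54254761e-01,3.22550900e-01
8.91250938e+00,7.67236532e+00,1.56823457e-01,2.98914988e-01
9.44060876e+00,6.41029742e+00,1.59169703e-01,2.76925824e-01
1.00000000e+01,5.35356332e+00,1.61303273e-01,2.56496818e-01
1.05925373e+01,4.46432340e+00,1.63234586e-01,2.37535371e-01
1.12201845e+01,3.72173138e+00,1.64974476e-01,2.19944773e-01
1.18850223e+01,3.10182562e+00,1.66533979e-01,2.03625896e-01
1.25892541e+01,2.58449882e+00,1.67924079e-01,1.88479359e-01
1.33352143e+01,2.15289004e+00,1.69155419e-01,1.74407976e-01
1.41253754e+01,1.79289089e+00,1.70238015e-01,1.61319246e-01
1.49623566e+01,1.49269930e+00,1.71181021e-01,1.49127468e-01
1.58489319e+01,1.24244511e+00,1.71992551e-01,1.37755409e-01
1.67880402e+01,1.03387603e+00,1.72679613e-01,1.27134983e-01
1.77827941e+01,8.60094278e-01,1.73248111e-01,1.17207413e-01
1.88364909e+01,7.15335791e-01,1.73702936e-01,1.07922604e-01
1.99526231e+01,5.94785159e-01,1.74048046e-01,9.92383384e-02
2.11348904e+01,4.94420575e-01,1.74286613e-01,9.11197769e-02
2.23872114e+01,4.10883938e-01,1.74421150e-01,8.35376681e-02
2.37137371e+01,3.41372070e-01,1.74453893e-01,7.64676015e-02
2.51188643e+01,2.83545642e-01,1.74386194e-01,6.98886490e-02
2.66072506e+01,2.35452939e-01,1.74219629e-01,6.37821055e-02
2.81838293e+01,1.95122160e-01,1.73955582e-01,5.81302418e-02
2.98538262e+01,1.61671475e-01,1.73595488e-01,5.29152104e-02
3.16227766e+01,1.33948049e-01,1.73140914e-01,4.81182545e-02
3.34965439e+01,1.10972531e-01,1.72593618e-01,4.37192014e-02
3.54813389e+01,9.19328295e-02,1.71955550e-01,3.96963459e-02
3.75837404e+01,7.61555799e-02,1.71228836e-01,3.60266698e-02
3.98107171e+01,6.30824762e-02,1.70415731e-01,3.26862920e-02
4.21696503e+01,5.22506348e-02,1.69518571e-01,2.96510019e-02
4.46683592e+01,4.32763061e-02,1.68539727e-01,2.68967898e-02
4.73151259e+01,3.58413626e-02,1.67481571e-01,2.44003004e-02
5.01187234e+01,2.96820915e-02,1.66346463e-01,2.21391308e-02
5.30884444e+01,2.45798990e-02,1.65136731e-01,2.00920664e-02
5.62341325e+01,2.03536003e-02,1.63854681e-01,1.82392174e-02
5.95662144e+01,1.68530262e-02,1.62502589e-01,1.65621373e-02
6.30957344e+01,1.39537203e-02,1.61082717e-01,1.50438762e-02
6.68343918e+01,1.15525418e-02,1.59597317e-01,1.36689920e-02
7.07945784e+01,9.56401971e-03,1.58048647e-01,1.24235057e-02
7.49894209e+01,7.91732948e-03,1.56438995e-01,1.12948101e-02
7.94328235e+01,6.55378639e-03,1.54770687e-01,1.02715674e-02
8.41395142e+01,5.42476740e-03,1.53046102e-01,9.34361377e-03
8.91250938e+01,4.48998828e-03,1.51267676e-01,8.50191422e-03
9.44060876e+01,3.71607537e-03,1.49437906e-01,7.73852200e-03
1.00000000e+02,3.07538165e-03,1.47559340e-01,7.04654954e-03
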