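-0.7466111426 -0.6646670517 0.0280982582
-0.3902941250 -0.9183018037 0.0662743787
0.0172490227 -0.9956513385 0.0915471647
-0.3575723784 0.9289610352 0.0957778123
0.9373742687 0.3334242335 0.1007857174
0.5855056552 -0.8027776239 0.1128326827
0.9656176331 -0.1979141591 0.1685602928
-0.9774249238 -0.1045384645 0.1836088992
-0.7185502740 0.6707782984 0.1836898966
-0.9430209408 0.2645308278 0.2018290027
0.3372556395 0.9060004065 0.2557770455
0.7582126879 -0.5931270469 0.2707652602
-0.8641060549 -0.3581992335 0.3535732385
-0.0955797694 0.9300377836 0.3548157673
-0.5121558043 -0.7635598725 0.3932845702
0.2867884614 -0.8690908556 0.4030303502
-0.1552623269 -0.8875717013 0.4337165951
0.8756937697 0.1970824167 0.4408162232
-0.7349245295 0.4760158094 0.4830060922
0.4524142160 0.7301066750 0.5121187561
0.7033169608 0.4859857163 0.5188093447
0.8259613473 -0.1045063975 0.5539551115
-0.3905620907 0.7300479800 0.5607951500
0.6800912257 -0.4536610863 0.5759058460
-0.6421508321 -0.4950106712 0.5853261862
-0.7950825610 0.1092847394 0.5965740246
0.0258333475 0.7520544664 0.6585945017
0.3747989845 -0.6018158266 0.7052258022
0.0125696207 -0.7017423065 0.7123199702
-0.4432195279 0.4446650051 0.7783504887
0.3972569000 0.4789733462 0.7827972209
-0.3199104449 -0.5175711995 0.7935851314
-0.5825738656 -0.1716008440 0.7944563181
0.5857332974 0.1000868711 0.8043003932
0.4246307497 -0.2654715860 0.8655712354
-0.4332359248 0.1296791534 0.8919024334
-0.0019575291 0.4467802662 0.8946415829
0.0073567852 -0.3416996142 0.9397804272
0.2250341389 0.1043357486 0.9687485163
-0.1190272443 -0.0049006609 0.9928788942
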