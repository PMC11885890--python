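-0.3708942043 -0.9268087138 0.0588480855
0.9867604317 -0.1460902013 0.0704379410
0.6977436147 -0.7128244977 0.0709583237
0.0221958691 0.9942729665 0.1045399995
-0.3721144847 0.9156247793 0.1521909127
-0.9213468305 -0.3551231234 0.1581378675
0.7786307288 0.5751995703 0.2507581355
-0.8228316507 0.5070437717 0.2566216829
-0.6615746044 -0.7003228507 0.2680801141
0.2447771695 -0.9183035865 0.3111312588
0.4987960915 0.7966165373 0.3414740862
-0.9323283204 0.0374862890 0.3596646787
0.7130921192 -0.5415854717 0.4451795215
-0.1675653606 -0.8583279470 0.4849690561
0.8633185908 0.1263512434 0.4885860970
-0.0009544794 0.8596245977 0.5109252782
0.8177221437 -0.1954725628 0.5414064766
-0.4577854124 0.6801150460 0.5726046109
-0.7511634938 -0.2841086250 0.5958487180
0.3574391931 -0.6679791394 0.6527182337
-0.7042924054 0.2791191410 0.6527363272
-0.4620008821 -0.5881387106 0.6638132584
0.5231944676 0.4863008397 0.6998421553
0.1147625466 0.5827724020 0.8044910723
-0.1128340771 -0.4869370578 0.8661182210
0.3552546704 -0.3437680478 0.8692627039
-0.4735192076 0.0060969820 0.8807623896
0.4095484060 0.1340222756 0.9023902331
-0.2009536677 0.3488927941 0.9153641033
-0.0307431857 -0.0504876233 0.9982513994
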