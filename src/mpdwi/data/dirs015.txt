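0.4603593955 -0.8801930988 0.1154527426
-0.9067759902 -0.3976087928 0.1402303512
0.8204645833 -0.5347317361 0.2022370835
-0.9684141675 0.1126762840 0.2224366319
-0.0355601936 -0.9738248583 0.2245008195
-0.6288136451 -0.7422217646 0.2317331481
-0.1657976983 0.8962759092 0.4113400271
0.7345062950 0.5304014090 0.4232905008
-0.6119597651 0.4006759292 0.6818827213
-0.0767033523 -0.6966087452 0.7133392264
0.6941952096 0.0509676320 0.7179800216
0.2557982140 0.6415916894 0.7231371777
0.4049677138 -0.4346954266 0.8043886106
-0.5205552306 -0.1523343316 0.8401288611
0.0046212392 0.1573860740 0.9875263378
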