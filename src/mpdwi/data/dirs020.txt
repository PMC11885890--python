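0.4790165705 0.8775972668 0.0191353729
-0.9733418834 -0.2150497033 0.0797446115
-0.8220411350 0.5536000779 0.1333241389
0.4874868976 -0.8534613563 0.1842830376
-0.0183458514 -0.9698134584 0.2431569158
-0.7128945358 -0.6285069940 0.3110632401
0.9432901571 -0.0375307756 0.3298410532
-0.2953827980 0.8900243848 0.3472831657
0.2533216823 0.8529004535 0.4564963765
0.7845781637 -0.4066644145 0.4680396982
0.7500204620 0.4671740477 0.4682069156
-0.7692847094 0.3415372995 0.5399567658
0.4086161899 -0.6003763467 0.6874453081
-0.5708340300 -0.3996961035 0.7172109418
-0.1273925008 -0.6799172916 0.7221382328
-0.1690397194 0.6062023425 0.7771385289
-0.5646173690 0.0197563615 0.8251163026
0.4600518147 0.3106879307 0.8317603847
0.1845667674 -0.2483208842 0.9509320937
-0.0429242357 0.1857190467 0.9816648846
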