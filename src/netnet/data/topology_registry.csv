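no,topology,auroc,sh0,sh1,sh2,sh3,sh4,sh5
1,MLP 14:14-10-1:1,0.6,1.367,1.561,1.428,1.428,1.428,1.428
2,MLP 15:15-12-1:1,0.7,1.424,1.571,1.492,1.492,1.492,1.492
3,MLP 18:18-8-13-1:1,0.8,1.518,2.074,1.509,1.704,1.704,1.704
4,MLP 16:16-8-10-1:1,0.7,1.486,1.881,1.415,1.532,1.532,1.532
5,MLP 18:18-8-1:1,0.8,1.564,1.759,1.423,1.481,1.481,1.481
6,MLP 16:16-12-13-1:1,0.8,1.358,1.481,1.481,1.481,1.481,1.481
7,MLP 11:11-10-1:1,0.7,1.394,1.806,1.395,1.395,1.395,1.395
8,LNN 16:16-1:1,0.6,0.881,2.637,2.637,2.637,2.637,2.637
9,LNN 17:17-1:1,0.6,0.895,2.788,2.788,2.788,2.788,2.788
10,LNN 18:18-1:1,0.6,0.908,2.938,2.938,2.938,2.938,2.938
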