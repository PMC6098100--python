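network,node_id,Sh_0,Sh_1,Sh_2,Sh_3,Sh_4,Sh_5
path3,a,0.528320833574,0.430827083454,0.528320833574,0.430827083454,0.528320833574,0.430827083454
path3,b,0.528320833574,0.389975000481,0.528320833574,0.389975000481,0.528320833574,0.389975000481
path3,c,0.528320833574,0.430827083454,0.528320833574,0.430827083454,0.528320833574,0.430827083454
star5,hub,0.464385618977,0.25754247591,0.464385618977,0.25754247591,0.464385618977,0.25754247591
star5,s1,0.464385618977,0.216096404744,0.464385618977,0.216096404744,0.464385618977,0.216096404744
star5,s2,0.464385618977,0.216096404744,0.464385618977,0.216096404744,0.464385618977,0.216096404744
star5,s3,0.464385618977,0.216096404744,0.464385618977,0.216096404744,0.464385618977,0.216096404744
star5,s4,0.464385618977,0.216096404744,0.464385618977,0.216096404744,0.464385618977,0.216096404744
k3,x,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574
k3,y,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574
k3,z,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574,0.528320833574
k22,p1,0.5,0.5,0.5,0.5,0.5,0.5
k22,p2,0.5,0.5,0.5,0.5,0.5,0.5
k22,q1,0.5,0.5,0.5,0.5,0.5,0.5
k22,q2,0.5,0.5,0.5,0.5,0.5,0.5
web_a,R1,0.271953923004,0.103702766465,0.183458447791,0.121840248896,0.162081283058,0.122831630707
web_a,R2,0.271953923004,0.150904444282,0.223428622871,0.186589301675,0.228252795726,0.192000383862
web_a,R3,0.271953923004,0.150904444282,0.262408295231,0.189738249258,0.245882857643,0.195291008889
web_a,R4,0.271953923004,0.171691247216,0.266265883699,0.180238678444,0.25000845657,0.188942931921
web_a,R5,0.271953923004,0.209157972513,0.296613056398,0.233908323886,0.29997784486,0.244986474041
web_a,R6,0.271953923004,0.455679509101,0.367771582235,0.395182989208,0.390579876437,0.366808916698
web_a,R7,0.271953923004,0.150904444282,0.238083327416,0.169961304498,0.237161787838,0.18316823352
web_a,R8,0.271953923004,0.209157972513,0.296613056398,0.233908323886,0.29997784486,0.244986474041
web_a,C1,0.271953923004,0.419548076877,0.309980043204,0.38507116398,0.311984591611,0.369778419328
web_a,C2,0.271953923004,0.0875611859564,0.179590305435,0.129483298733,0.143411747139,0.140991034135
web_a,C3,0.271953923004,0.0875611859564,0.179590305435,0.129483298733,0.143411747139,0.140991034135
web_a,C4,0.271953923004,0.433522348261,0.357966736929,0.432308027034,0.372920405437,0.433940924702
web_a,C5,0.271953923004,0.327677223893,0.301705640673,0.341901559158,0.303229557535,0.350590774297
web_a,C6,0.271953923004,0.365522539035,0.255029054743,0.364443366273,0.278744467684,0.360483400005
web_b,R1,0.216096404744,0.243533621343,0.219436024264,0.225761346841,0.224581935975,0.222112844744
web_b,R2,0.216096404744,0.18307400202,0.21785057003,0.217802870954,0.222814708318,0.225057407401
web_b,R3,0.216096404744,0.13943516508,0.169466025583,0.160278283842,0.168328706503,0.165729031135
web_b,R4,0.216096404744,0.0984481765935,0.129795244305,0.100792349227,0.113582136469,0.101941578129
web_b,R5,0.216096404744,0.29874687506,0.213686969022,0.261643335194,0.219685815236,0.245232554061
web_b,R6,0.216096404744,0.293336556072,0.308788228745,0.304130614987,0.312385154958,0.308777727375
web_b,R7,0.216096404744,0.220855489639,0.215054795859,0.217179405304,0.222788880922,0.219972768583
web_b,R8,0.216096404744,0.148736457145,0.176719646695,0.172681980295,0.173257263537,0.175483438148
web_b,R9,0.216096404744,0.280272419562,0.279953585228,0.273269183622,0.276345049166,0.271662897656
web_b,R10,0.216096404744,0.177636209781,0.185754247591,0.169324676593,0.175333037002,0.169425120254
web_b,C1,0.216096404744,0.284069682974,0.250142036886,0.275886921952,0.267477787282,0.273112477895
web_b,C2,0.216096404744,0.274475951612,0.220619398687,0.244849574102,0.222827512636,0.234136716769
web_b,C3,0.216096404744,0.0984481765935,0.143609027818,0.0972047639915,0.122690210667,0.100307412198
web_b,C4,0.216096404744,0.148736457145,0.17255777528,0.170163869439,0.168559891232,0.171897665194
web_b,C5,0.216096404744,0.13943516508,0.173209239165,0.168181838118,0.169206516806,0.171431980261
web_b,C6,0.216096404744,0.227849422529,0.214089947468,0.224017381138,0.218916211018,0.224986966643
web_b,C7,0.216096404744,0.302293434625,0.291018902571,0.303605347056,0.301937126808,0.308356500683
web_b,C8,0.216096404744,0.191040104197,0.181724320326,0.176168274744,0.170332971535,0.172870666681
web_b,C9,0.216096404744,0.227849422529,0.24642575697,0.226599172882,0.239273826433,0.226002173813
web_b,C10,0.216096404744,0.196229755469,0.235574973418,0.218623250784,0.234015729206,0.223239512529
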