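peak_no,rt_min,ki,label,chc_class,chain,methyls,double_bonds,diagnostic_ions,male_mean,male_se,female_mean,female_se,sex_diff
1,34.04,2480,7-C_25:1,alkene,25,,7,83;97;111;350,0.6,0.1,0.6,0.1,
2,34.29,2500,n-C_25,n_alkane,25,,,352,17.5,1.6,11.1,1.4,male**
3,35.21,2572,3-meC_25,monomethyl,25,3,,337;366,1.4,0.1,1.3,0.1,
4,35.56,2600,n-C_26,n_alkane,26,,,366,3.1,0.4,2.7,0.4,
5,36.27,2657,4-meC_26,monomethyl,26,4,,43;71;337;380,0.4,0.0,0.6,0.1,
6,36.52,2677,9-C_27:1,alkene,27,,9,83;97;111;378,16.8,1.7,15.8,2.0,
7,36.6,2684,7-C_27:1,alkene,27,,7,83;97;111;378,5.3,0.4,4.8,0.6,
8,36.8,2700,n-C_27,n_alkane,27,,,380,21.8,1.6,19.5,1.7,
9,37.19,2733,11-meC_27,monomethyl,27,11,,168;252,0.7,0.1,0.9,0.1,
10,37.29,2741,7-meC_27,monomethyl,27,7,,112;309,0.2,0.0,0.4,0.0,female**
11,37.39,2750,5-meC_27,monomethyl,27,5,,85;337,2.0,0.1,2.4,0.2,
12,37.68,2774,3-meC_27,monomethyl,27,3,,365;394,7.0,0.5,7.9,0.5,
13,37.99,2800,n-C_28,n_alkane,28,,,394,1.7,0.2,2.0,0.2,
14,38.09,2809,"3,7-dimeC_27",dimethyl,27,3;7,,393;379;126;308,1.6,0.1,1.7,0.1,
15,38.67,2858,4-meC_28,monomethyl,28,4,,43;71;365,1.1,0.1,1.7,0.2,female*
16,38.92,2879,9-C_29:1,alkene,29,,9,406;83;97;111,2.0,0.2,2.3,0.2,
17,38.99,2885,7-C_29:1,alkene,29,,7,406;71;83;97;111,1.4,0.1,1.6,0.1,
18,39.16,2900,n-C_29,n_alkane,29,,,408,2.4,0.1,2.8,0.2,
19,39.5,2930,13-meC_29,monomethyl,29,13,,196;224;252;407,1.1,0.3,1.6,0.4,
20,39.6,2938,7-meC_29,monomethyl,29,7,,112;337;407,1.2,0.2,2.0,0.3,female*
21,39.71,2948,5-meC_29,monomethyl,29,5,,85;365;407,1.2,0.2,1.6,0.2,
22,39.83,2958,"9,13-dimeC_29",dimethyl,29,9;13,,421;323;252;211;140,0.8,0.2,1.1,0.3,
23,40.04,2977,"5,X-dimeC_29",dimethyl,29,5;X,,85;196;211;379;421,2.5,0.7,4.2,0.9,
24,40.31,3000,n-C_30,n_alkane,30,,,422,0.5,0.1,0.5,0.1,
25,41.15,3073,7-C_31:1,alkene,31,,7,83;97;111;434,0.5,0.1,0.5,0.1,
26,41.71,3121,15-meC_31,monomethyl,31,15,,196;224;252,1.6,0.5,2.6,0.6,
27,41.84,3133,7-meC_31,monomethyl,31,7,,112;365;436,0.4,0.1,0.7,0.2,
28,42.04,3150,"11,15-dimeC_31",dimethyl,31,11;15,,168;239;252;323,0.7,0.2,1.1,0.3,
29,42.19,3163,4-meC_31,monomethyl,31,4,,71;379;450,0.9,0.2,1.5,0.4,
30,42.3,3173,"5,17-dimeC_31",dimethyl,31,5;17,,85;126;168;225;267;407,1.7,0.5,2.7,0.7,
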