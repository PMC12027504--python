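peak_no,label,MJHL_mean,MJHL_se,WDLN_mean,WDLN_se,GHIM_mean,GHIM_se,YCHL_mean,YCHL_se,EDJL_mean,EDJL_se,ARIM_mean,ARIM_se
1,7-C_25:1,0.7,0.1,0.9,0.1,0.1,0.1,0.1,0.0,0.7,0.1,0.8,0.1
2,n-C_25,12.3,1.3,17.1,1.9,6.5,0.9,5.2,0.8,26.8,1.3,13.4,0.8
3,3-meC_25,1.7,0.1,1.6,0.1,0.8,0.1,0.7,0.1,1.7,0.1,1.5,0.2
4,n-C_26,5.6,0.5,4.2,0.4,1.2,0.2,0.9,0.1,2.6,0.1,1.6,0.3
5,4-meC_26,0.7,0.1,0.5,0.1,0.4,0.1,0.8,0.5,0.3,0.1,0.5,0.1
6,9-C_27:1,13.5,0.8,18.6,1.4,10.1,1.4,4.4,0.4,17.6,0.7,39.4,2.2
7,7-C_27:1,5.3,0.5,7.4,0.7,2.4,0.3,1.8,0.2,6.1,0.5,6.7,0.6
8,n-C_27,23.5,1.8,27.6,1.2,14.1,1.4,8.1,1.1,29.3,1.0,12.0,0.9
9,11-meC_27,1.2,0.2,0.3,0.1,1.5,0.1,1.7,0.2,0.02,0.0,0.5,0.1
10,7-meC_27,0.3,0.1,0.1,0.1,0.5,0.1,0.5,0.1,0.1,0.1,0.3,0.1
11,5-meC_27,2.9,0.2,1.8,0.2,2.7,0.2,2.7,0.3,1.3,0.1,1.9,0.2
12,3-meC_27,11.2,0.3,7.3,0.4,8.5,0.5,7.0,0.8,4.7,0.4,5.0,0.6
13,n-C_28,3.3,0.3,2.2,0.2,1.5,0.2,2.2,0.5,0.9,0.1,0.5,0.1
14,"3,7-dimeC_27",2.2,0.2,1.2,0.1,2.2,0.3,1.9,0.1,1.3,0.1,1.6,0.2
15,4-meC_28,1.7,0.1,1.0,0.2,1.8,0.1,3.2,0.3,0.2,0.1,1.1,0.1
16,9-C_29:1,1.5,0.2,2.0,0.2,2.8,0.2,2.2,0.2,1.7,0.1,3.5,0.3
17,7-C_29:1,1.2,0.1,1.3,0.1,2.1,0.2,2.3,0.1,0.8,0.1,1.8,0.3
18,n-C_29,3.2,0.3,3.1,0.3,2.4,0.2,2.4,0.2,2.7,0.2,1.0,0.1
19,13-meC_29,0.6,0.2,nd,nd,3.4,0.3,4.3,0.3,nd,nd,0.6,0.1
20,7-meC_29,1.4,0.2,0.6,0.4,2.9,0.3,4.2,0.2,0.1,0.1,1.0,0.1
21,5-meC_29,1.7,0.1,0.8,0.2,2.2,0.2,3.1,0.2,0.2,0.1,0.6,0.1
22,"9,13-dimeC_29",nd,nd,nd,nd,2.5,0.3,3.4,0.4,nd,nd,0.2,0.1
23,"5,X-dimeC_29",1.5,0.4,0.3,0.1,8.2,1.0,10.6,0.3,0.1,0.1,1.4,0.2
24,n-C_30,0.8,0.1,nd,nd,1.2,0.2,0.8,0.1,nd,nd,0.4,0.1
25,7-C_31:1,0.3,0.1,0.1,0.1,0.9,0.1,1.3,0.19,0.2,0.1,0.5,0.2
26,15-meC_31,0.7,0.1,nd,nd,4.3,0.4,8.0,1.08,0.3,0.1,0.7,0.1
27,7-meC_31,nd,nd,nd,nd,1.0,0.1,2.1,0.14,0.2,0.1,0.1,0.1
28,"11,15-dimeC_31",nd,nd,nd,nd,2.4,0.3,3.4,0.36,nd,nd,0.2,0.0
29,4-meC_31,0.6,0.1,nd,nd,3.5,0.5,3.2,0.20,nd,nd,0.5,0.1
30,"5,17-dimeC_31",0.5,0.1,nd,nd,6.0,0.6,7.2,0.3,nd,nd,0.7,0.1
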