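id,bsa,sex,age,sbp_rest,sbp_ex,dbp_rest,dbp_ex,hr_rest,hr_ex,sv_rest,sv_ex,q_asc_rest,q_asc_ex,q_desc_rest,q_desc_ex,pg_rest,pg_ex,wss_rest,wss_ex,sfd_asc_rest,sfd_asc_ex,sfd_desc_rest,sfd_desc_ex,nfd_asc_rest,nfd_asc_ex,nfd_desc_rest,nfd_desc_ex
1,1.51,F,32,126,187,65,125,50,101,84.9,69.9,338,411,231,352,10,22,5.5,7.3,0.163,0.16,0.633,0.576,0.036,0.035,0.123,0.125
2,1.87,M,21,139,149,67,67,83,129,84.0,87.3,459,581,305,433,10,23,12.8,20.6,0.201,0.261,0.28,0.281,0.015,0.066,0.113,0.163
3,1.78,F,12,102,114,58,55,85,132,89.3,84.7,456,466,229,269,50,70,44.7,33.7,1.483,1.253,0.303,0.223,0.197,0.221,0.036,0.076
4,1.87,M,18,150,163,76,72,85,150,88.7,100.2,518,782,301,317,13,25,30.8,41.2,0.326,0.26,0.264,0.319,0.089,0.035,0.089,0.13
5,1.83,M,21,136,172,63,90,85,119,93.2,106.3,551,645,292,378,11,18,8.3,10.4,0.157,0.152,0.199,0.207,0.055,0.055,0.051,0.055
6,1.51,M,13,145,149,70,69,94,125,80.9,83.0,445,533,199,210,55,78,34.7,47.4,0.217,0.312,0.853,0.936,0.063,0.047,0.192,0.228
7,1.07,M,8,133,160,66,71,83,115,55.0,55.1,243,250,128,154,43,55,9.1,10.5,0.187,0.142,1.825,1.673,0.012,0.025,0.074,0.068
8,1.98,M,15,129,142,58,61,44,51,133.2,116.8,464,635,294,384,23,44,28.6,30.5,0.594,0.284,0.136,0.138,0.111,0.063,0.115,0.079
9,1.06,M,10,129,134,57,71,68,99,56.0,68.3,303,440,117,164,12,33,19.1,26.8,0.428,0.321,0.357,0.43,0.076,0.03,0.198,0.208
10,1.65,F,33,120,168,68,82,66,74,77.3,76.0,341,411,226,175,5,3,11.1,8.8,1.286,0.96,0.226,0.264,0.153,0.058,0.034,0.043
11,1.64,F,27,123,138,67,86,57,87,89.6,83.3,423,470,176,260,3,5,8.3,10.2,0.947,0.866,0.244,0.37,0.102,0.147,0.155,0.161
12,1.53,F,14,115,169,54,70,65,95,71.5,73.0,318,443,188,253,45,63,37.0,59.9,0.173,0.173,0.277,0.14,0.021,0.021,0.069,0.156
13,2.2,M,51,120,134,71,67,65,93,95.8,90.3,493,526,226,258,4,4,20.5,23.4,0.716,0.677,0.789,0.757,0.212,0.163,0.163,0.194
14,1.32,M,14,87,204,52,98,79,89,71.6,78.5,434,431,220,284,22,34,38.7,38.3,0.324,0.313,0.116,0.115,0.142,0.129,0.017,0.017
15,2.14,M,59,191,185,93,85,69,76,89.0,107.1,501,632,218,264,5,8,5.2,8.1,0.176,0.5,1.523,2.942,0.018,0.045,0.209,0.023
16,1.69,M,15,136,264,61,128,99,62,82.2,92.4,453,603,173,229,15,25,20.3,35.3,0.603,0.553,0.617,0.76,0.135,0.154,0.143,0.194
17,1.54,M,13,120,126,56,71,76,86,73.5,82.4,411,584,204,340,12,22,22.5,35.0,0.435,0.363,0.337,0.286,0.051,0.046,0.166,0.126
18,0.82,M,8,126,138,69,73,94,112,45.3,48.3,269,275,86,123,2,7,22.2,22.7,0.079,0.078,0.356,0.411,0.027,0.027,0.086,0.07
19,1.96,F,17,142,123,65,66,85,96,108.3,109.9,408,582,270,347,13,16,21.6,25.9,0.509,0.236,0.397,0.258,0.124,0.106,0.06,0.058
20,1.61,F,29,100,154,60,69,67,103,69.2,70.0,312,426,189,304,7,15,5.6,11.6,0.241,0.486,0.241,0.49,0.048,0.127,0.052,0.126
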