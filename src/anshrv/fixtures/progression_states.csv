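state,lf_nu,hf_nu,lf_hf,sd1,sd2,sd2_sd1,sdnn,rmssd
1,35.70,63.75,0.56,127,130.6,1.02,128.8,180
2,57,42,1.37,59.7,95.5,1.60,79.5,84.1
3,76.35,23.62,3.64,32,75.1,2.35,57.6,45.2
4,83.38,16.61,5.02,18.1,57.4,3.17,42.5,25.5
5,86.34,13.68,6.30,13.6,47.4,3.41,34.8,19.2
6,87.80,12.14,7.23,11,39.7,3.60,29.1,15.4
7,88.726,11.27,7.80,8.9,33.2,3.71,24.3,12.6
8,89.33,10.66,8.37,7.3,27.7,3.77,20.3,10.3
9,89.90,10,8.92,6,23,3.85,16.9,8.4
10,90.68,9.32,9.74,4.7,18.6,3.95,13.6,6.7
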