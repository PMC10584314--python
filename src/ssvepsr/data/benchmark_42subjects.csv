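subject,acc_cca,itr_cca,acc_fbcca,itr_fbcca,acc_car_ussr,itr_car_ussr,acc_pca_ussr,itr_pca_ussr
S1,94.29,135.68,82.86,107.89,8.57,1.68,54.29,54.27
S2,28.57,18.97,34.29,25.76,80.00,101.70,42.86,37.11
S3,77.14,95.73,68.57,78.97,74.29,89.96,74.29,89.96
S4,48.57,45.40,54.29,54.27,57.14,58.91,48.57,45.40
S5,88.57,121.05,65.71,73.72,54.29,54.27,22.86,12.87
S6,94.29,135.68,77.14,95.73,88.57,121.05,77.14,95.73
S7,74.29,89.96,82.86,107.89,20.00,10.12,57.14,58.91
S8,77.14,95.73,65.71,73.72,5.71,0.50,62.86,68.64
S9,68.57,78.97,60.00,63.70,88.57,121.05,54.29,54.27
S10,34.29,25.76,40.00,33.18,77.14,95.73,37.14,29.39
S11,42.86,37.11,57.14,58.91,62.86,68.64,45.71,41.18
S12,34.29,25.76,68.57,78.97,25.71,15.83,71.43,84.38
S13,31.43,22.28,45.71,41.18,28.57,18.97,65.71,73.72
S14,57.14,58.91,65.71,73.72,77.14,95.73,60.00,63.70
S15,42.86,37.11,71.43,84.38,28.57,18.97,71.43,84.38
S16,62.86,68.64,62.86,68.64,82.86,107.89,85.71,114.32
S17,74.29,89.96,62.86,68.64,82.86,107.89,77.14,95.73
S18,62.86,68.64,65.71,73.72,74.29,89.96,57.14,58.91
S19,85.71,114.32,74.29,89.96,94.29,135.68,65.71,73.72
S20,74.29,89.96,65.71,73.72,2.86,0,37.14,29.39
S21,60.00,63.70,65.71,73.72,51.43,49.76,77.14,95.73
S22,68.57,78.97,68.57,78.97,94.29,135.68,65.71,73.72
S23,65.71,73.72,71.43,84.38,88.57,121.05,48.57,45.40
S24,82.86,107.89,91.43,128.14,85.71,114.32,74.29,89.96
S25,51.43,49.76,60.00,63.70,45.71,41.18,37.14,29.39
S26,74.29,89.96,74.29,89.96,31.43,22.28,65.71,73.72
S27,62.86,68.64,60.00,63.70,8.57,1.68,60.00,63.70
S28,68.57,78.97,71.43,84.38,25.71,15.83,42.86,37.11
S29,40.00,33.18,80.00,101.70,82.86,107.89,57.14,58.91
S30,11.43,3.32,40.00,33.18,8.57,1.68,45.71,41.18
S31,62.86,68.64,68.57,78.97,2.86,0,37.14,29.39
S32,91.43,128.14,77.14,95.73,94.29,135.68,82.86,107.89
S33,40.00,33.18,77.14,95.73,85.71,114.32,28.57,18.97
S34,85.71,114.32,77.14,95.73,17.14,7.59,20.00,10.12
S35,71.43,84.38,77.14,95.73,57.14,58.91,60.00,63.70
S36,68.57,78.97,68.57,78.97,2.86,0,62.86,68.64
S37,54.29,54.27,65.71,73.72,82.86,107.89,54.29,54.27
S38,51.43,49.76,60.00,63.70,71.43,84.38,68.57,78.97
S39,40.00,33.18,62.86,68.64,8.57,1.68,31.43,22.28
S40,42.86,37.11,54.29,54.27,77.14,95.73,17.14,7.59
S41,57.14,58.91,65.71,73.72,5.71,0.50,40.00,33.18
S42,62.86,68.64,62.86,68.64,57.14,58.91,62.86,68.64
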