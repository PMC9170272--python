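dyad_id,role,session_index,analytic,clout,authentic,tone
B,client,1,7.2,11.6,95.16,59.63
B,client,2,4.59,14.94,92.75,60.95
B,client,3,8.49,15.99,92.94,51.18
B,client,4,6.76,16.41,88.04,50.45
B,client,5,5.26,19.92,83.7,81.93
B,client,6,4.23,38.41,73.35,34.36
B,client,7,5.38,9.82,92.72,41.34
B,client,8,1.89,8.74,97.23,48.31
B,client,9,5.35,20.47,92.83,50.54
B,client,10,3.22,20.56,85.43,44.17
B,client,11,5.08,8.66,95.22,75.85
B,client,12,6.09,16.98,86.3,43.6
B,client,13,5.75,32.15,76.13,64.51
B,client,14,6.27,18.84,85.88,78.6
B,therapist,1,15.4,90.23,50.24,58.7
B,therapist,2,11.88,92.89,51.82,62.78
B,therapist,3,17.9,88.02,54.4,64.12
B,therapist,4,16.87,93.37,46.92,61.21
B,therapist,5,9.17,94.7,47.28,74.81
B,therapist,6,15.01,91.05,44.97,74.45
B,therapist,7,11.37,87.56,59.66,46.79
B,therapist,8,12.74,90.6,57.11,72.19
B,therapist,9,17.91,88.03,40.12,51.58
B,therapist,10,12.06,90.37,39.1,58.91
B,therapist,11,19.2,92.56,56.03,75.48
B,therapist,12,16.37,92.4,48.83,74.9
B,therapist,13,15.69,80.49,60.4,65.98
B,therapist,14,24.48,87.23,43.96,72.94
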