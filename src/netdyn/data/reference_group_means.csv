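protocol,state,network,group,fractional_occupancy_mean,fractional_occupancy_sd,n_occurrences_mean,n_occurrences_sd,mean_lifetime_mean,mean_lifetime_sd,mean_interval_mean,mean_interval_sd
rest,1,Sensorimotor,control,19.17,5.29,420.14,103.48,182.61,27.22,0.90,0.38
rest,1,Sensorimotor,case,18.18,8.19,333.88,124.96,210.29,63.41,1.20,0.57
rest,2,Frontoparietal,control,0.33,0.30,7.71,8.32,223.87,267.67,95.30,89.49
rest,2,Frontoparietal,case,0.40,0.50,5.75,6.25,110.54,121.94,147.16,208.53
rest,3,Right sensorimotor,control,8.46,2.79,196.57,48.04,156.72,23.71,1.91,0.59
rest,3,Right sensorimotor,case,11.40,5.63,245.38,95.14,160.27,29.76,1.54,0.56
rest,4,Early visual,control,10.01,2.92,243.00,59.99,153.94,36.95,1.59,0.49
rest,4,Early visual,case,16.93,5.72,320.38,104.11,210.47,55.39,1.20,0.41
rest,5,Higher-order visual,control,18.94,11.24,275.86,93.12,287.90,141.73,1.53,0.59
rest,5,Higher-order visual,case,14.80,9.15,198.38,124.28,307.93,130.13,5.80,8.20
rest,6,Early visual II,control,29.17,12.62,563.57,145.77,208.72,51.95,0.59,0.24
rest,6,Early visual II,case,20.43,9.07,401.50,130.53,191.89,49.21,0.88,0.33
rest,7,Left temporal,control,8.68,2.92,220.14,54.82,139.90,27.31,1.73,0.49
rest,7,Left temporal,case,11.41,5.76,250.25,112.14,159.96,51.90,1.55,0.59
rest,8,Frontotemporoparietal,control,5.22,3.24,97.43,44.19,202.97,56.16,4.74,1.78
rest,8,Frontotemporoparietal,case,6.43,4.66,105.38,55.27,203.18,93.75,6.72,9.19
task,1,Parietal,control,4.31,9.05,37.43,73.57,105.78,146.26,128.96,68.34
task,1,Parietal,case,12.07,12.61,68.19,74.73,315.48,259.69,57.68,56.94
task,2,Frontoparietal,control,2.62,2.60,11.64,8.39,222.03,73.57,38.96,37.60
task,2,Frontoparietal,case,13.40,19.29,20.61,10.71,731.25,1021.40,20.26,12.31
task,3,Fronto-occipital,control,10.17,7.60,89.36,66.26,224.41,75.67,12.91,16.74
task,3,Fronto-occipital,case,11.11,6.94,100.53,69.57,319.86,44.20,26.03,26.96
task,4,Frontotemporal,control,21.32,22.01,69.21,33.46,398.80,250.83,12.91,4.97
task,4,Frontotemporal,case,15.95,12.91,51.86,17.47,352.22,132.43,10.22,10.06
task,5,Right temporoparietal,control,13.28,15.58,94.50,113.89,198.52,166.69,70.38,67.02
task,5,Right temporoparietal,case,17.72,12.63,138.53,116.29,264.83,143.91,40.27,50.34
task,6,Bilateral temporal,control,18.42,8.47,99.57,27.55,323.73,78.18,2.45,1.07
task,6,Bilateral temporal,case,8.33,5.12,61.47,28.13,324.60,102.58,19.26,24.25
task,7,Frontoparietal II,control,11.70,10.98,82.07,63.75,255.65,139.93,25.71,38.25
task,7,Frontoparietal II,case,13.03,9.02,90.69,56.92,291.51,149.83,25.82,26.59
task,8,Fronto-occipital II,control,19.05,10.49,99.29,31.10,301.25,107.02,2.97,2.00
task,8,Fronto-occipital II,case,8.40,6.26,56.19,26.83,309.62,101.75,19.83,24.67
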