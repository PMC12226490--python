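scorer,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand,hand
individuals,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M1,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2,M2
bodyparts,nose,nose,nose,left_ear,left_ear,left_ear,right_ear,right_ear,right_ear,tail_base,tail_base,tail_base,tail_end,tail_end,tail_end,nose,nose,nose,left_ear,left_ear,left_ear,right_ear,right_ear,right_ear,tail_base,tail_base,tail_base,tail_end,tail_end,tail_end
coords,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood,x,y,likelihood
0,1.0,0.5,0.5,2.0,0.5,0.55,3.0,0.5,0.6,4.0,0.5,0.65,5.0,0.5,0.7,1.0,100.5,0.5,2.0,100.5,0.55,3.0,100.5,0.6,4.0,100.5,0.65,5.0,100.5,0.7
1,11.0,1.5,0.51,12.0,1.5,0.56,13.0,1.5,0.61,14.0,1.5,0.66,15.0,1.5,0.71,11.0,101.5,0.51,12.0,101.5,0.56,13.0,101.5,0.61,14.0,101.5,0.66,15.0,101.5,0.71
2,21.0,2.5,0.52,22.0,2.5,0.57,23.0,2.5,0.62,24.0,2.5,0.67,25.0,2.5,0.72,21.0,102.5,0.52,22.0,102.5,0.57,23.0,102.5,0.62,24.0,102.5,0.67,25.0,102.5,0.72
3,31.0,3.5,0.53,32.0,3.5,0.58,33.0,3.5,0.63,34.0,3.5,0.68,35.0,3.5,0.73,31.0,103.5,0.53,32.0,103.5,0.58,33.0,103.5,0.63,34.0,103.5,0.68,35.0,103.5,0.73
4,41.0,4.5,0.54,42.0,4.5,0.59,43.0,4.5,0.64,44.0,4.5,0.69,45.0,4.5,0.74,41.0,104.5,0.54,42.0,104.5,0.59,43.0,104.5,0.64,44.0,104.5,0.69,45.0,104.5,0.74
5,51.0,5.5,0.55,52.0,5.5,0.6,53.0,5.5,0.65,54.0,5.5,0.7,55.0,5.5,0.75,51.0,105.5,0.55,52.0,105.5,0.6,53.0,105.5,0.65,54.0,105.5,0.7,,,
6,61.0,6.5,0.56,62.0,6.5,0.61,63.0,6.5,0.66,64.0,6.5,0.71,65.0,6.5,0.76,61.0,106.5,0.56,62.0,106.5,0.61,63.0,106.5,0.66,64.0,106.5,0.71,65.0,106.5,0.76
7,71.0,7.5,0.57,72.0,7.5,0.62,73.0,7.5,0.67,74.0,7.5,0.72,75.0,7.5,0.77,71.0,107.5,0.57,72.0,107.5,0.62,73.0,107.5,0.67,74.0,107.5,0.72,75.0,107.5,0.77
8,81.0,8.5,0.58,82.0,8.5,0.63,83.0,8.5,0.68,84.0,8.5,0.73,85.0,8.5,0.78,81.0,108.5,0.58,82.0,108.5,0.63,83.0,108.5,0.68,84.0,108.5,0.73,85.0,108.5,0.78
9,91.0,9.5,0.59,92.0,9.5,0.64,93.0,9.5,0.69,94.0,9.5,0.74,95.0,9.5,0.79,91.0,109.5,0.59,92.0,109.5,0.64,93.0,109.5,0.69,94.0,109.5,0.74,95.0,109.5,0.79
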