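patient,red,green,blue,L,a,b,ITA,diagnosis
1,195.36,61.56,68.57,46.27,53.46,26.45,-8.02,CHERRY
2,234.29,130.99,116.65,65.79,38.13,25.28,31.98,CHERRY
3,180.92,83.31,75.92,47.71,39,23.43,-5.58,CHERRY
4,179.48,69.44,73.92,44.86,45.07,20.86,-13.83,CHERRY
5,149.01,29.35,23.61,32.59,48.2,35.04,-26.42,CHERRY
6,252.19,108.81,64.77,63.35,52.27,50.71,14.75,CHERRY
7,131.08,66.53,53.68,36.09,26.39,20.32,-34.4,CHERRY
8,186.13,54.34,70.36,43.61,53.41,21.63,-16.45,CHERRY
9,145.06,75.35,54.33,40.2,27.35,25.57,-20.96,CHERRY
10,138.91,78.28,72.55,40.32,24.8,14.52,-33.69,CHERRY
11,193.87,71.17,69.33,47.51,48.99,27.5,-5.17,CHERRY
12,188.32,60.31,85.61,45.17,52.88,14.39,-18.56,MCC
13,167.45,73.89,89.13,44.05,39.96,10.13,-30.44,MCC
14,163.26,47.67,58.33,38.22,47.87,21.27,-28.98,MCC
15,202.65,84.05,103.24,51.81,48.76,13.26,7.79,MCC
16,196.32,111.59,116.04,56.62,33.9,12.29,28.33,MCC
17,186.11,89.27,97.74,50.12,39.84,13.8,0.5,MCC
18,171.24,79.15,86.69,45.61,38.44,13.88,-17.55,MCC
19,169.73,67.73,82.08,43.1,43.11,13.22,-27.55,MCC
20,209.73,88.73,112.24,53.96,49.83,11.06,19.69,MCC
21,176.62,114.04,113.53,54.61,24.66,10.55,23.59,MCC
22,196.77,84.82,97.26,50.89,45.82,15.41,3.31,MCC
23,195.47,120.94,105.15,58.37,27.35,20.94,21.78,BCC/SCC
24,205.99,147.21,133.26,66.33,20.35,16.19,45.25,BCC/SCC
25,164.11,80.72,77.92,44.66,34.09,17.72,-16.78,BCC/SCC
26,187.8,110.03,107.45,54.97,30.52,14.81,18.54,BCC/SCC
27,196.88,127.15,133.94,60.6,27.89,7.59,54.4,BCC/SCC
28,149.7,83.91,79.4,43.29,26.77,14.62,-24.65,BCC/SCC
29,141.82,85.64,87.17,42.8,23.5,9.04,-38.56,BCC/SCC
30,114.46,78.18,65.55,36.88,13.57,13.61,-43.96,BCC/SCC
31,145.93,100.11,92.25,47,17.46,11.91,-14.15,BCC/SCC
32,146.09,84.64,68.31,42.73,23.73,20.49,-19.53,BCC/SCC
33,221.22,146.6,126.2,67.77,25.81,22.37,38.47,BCC/SCC
34,198.8,139.69,135.18,63.78,21.91,11.43,50.33,BCC/SCC
35,117.62,43.26,50.63,28.92,33.27,12.43,-59.48,HEMANGIOMA
36,144.72,81.6,92.8,42.39,27.69,5.06,-56.38,HEMANGIOMA
37,134.11,80.22,82.49,40.35,22.89,8.32,-49.22,HEMANGIOMA
38,166.23,81.71,90.37,45.45,35.61,11.31,-21.91,HEMANGIOMA
39,152.46,83.97,98.08,44.15,30.06,4.48,-52.59,HEMANGIOMA
40,139.55,49.53,70.75,34.46,40.06,7.55,-64.09,HEMANGIOMA
41,231.25,113.34,123.18,61.96,46.52,16.32,36.23,HEMANGIOMA
42,147.37,80.24,93.73,42.48,29.61,4.67,-58.17,HEMANGIOMA
43,157.88,74.23,74.29,42.28,34.78,16.58,-24.96,HEMANGIOMA
44,136.11,45.77,52.48,32.77,39,16.94,-45.48,HEMANGIOMA
45,178.88,98.04,86.68,50.68,31.4,20.94,1.86,HEMANGIOMA
46,147.18,49.5,44.21,35.28,40.74,25.73,-29.76,HEMANGIOMA
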