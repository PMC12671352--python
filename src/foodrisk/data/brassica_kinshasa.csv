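sample_id,site,Ti,V,Cr,Mn,Fe,Co,Ni,Cu,Zn,As,Se,Mo,Ag,Cd,Sn,Sb,Ba,Pb,Hg
LOD,,0.098,0.024,0.000,0.150,0.681,0.025,0.000,1.516,2.033,0.049,0.063,1.091,,,,,,,0.005
CS1A,Cecomaf,4.34,0.75,1.16,171.20,519.24,0.24,2.30,85.42,844.94,0.10,0.00,0.66,0.04,2.24,0.92,0.16,107.85,6.67,0.030
CS1M,Cecomaf,5.32,0.68,1.31,310.08,483.03,0.14,2.15,56.78,74.54,0.07,0.00,0.27,0.01,0.70,1.93,0.18,30.46,11.34,0.027
CS2A,Cecomaf,3.10,0.43,0.59,1154.11,268.31,0.34,1.65,77.74,522.84,0.05,0.15,0.17,0.01,1.29,0.92,0.10,29.55,3.97,0.050
CS2M,Cecomaf,4.58,1.14,1.35,230.86,603.46,0.17,1.74,68.84,74.18,0.12,0.13,0.59,0.01,0.25,0.60,0.12,14.67,11.51,0.033
CS2P,Cecomaf,6.21,0.58,1.35,194.61,527.99,0.61,6.18,115.39,814.78,0.07,0.07,1.90,0.04,2.95,1.09,0.18,137.91,7.29,0.054
CS3A,Cecomaf,11.66,0.72,1.08,129.60,572.69,0.68,3.55,32.05,615.81,0.08,0.13,2.58,0.03,2.15,1.12,0.12,92.58,5.84,0.051
CS3M,Cecomaf,3.84,0.53,0.92,68.75,435.42,0.11,2.31,27.29,81.34,0.06,0.09,1.43,0.00,0.38,1.02,0.20,14.83,5.93,0.023
CS3P,Cecomaf,34.50,3.12,3.73,124.83,1513.08,0.35,5.16,23.39,289.07,0.26,0.19,2.43,0.03,0.78,1.08,0.26,42.05,30.94,0.042
CS4A,Cecomaf,12.06,0.63,1.12,65.34,594.98,0.19,2.37,22.51,257.88,0.07,0.11,1.41,0.01,0.75,0.83,0.15,44.29,4.31,0.058
CS4M,Cecomaf,5.05,0.35,0.69,126.38,273.16,0.06,1.41,23.59,49.86,0.04,0.00,2.72,0.00,0.11,0.89,0.10,5.18,2.39,0.013
CS4P,Cecomaf,36.59,4.27,4.55,377.68,1924.69,0.44,2.87,93.92,96.93,0.31,0.19,0.95,0.02,0.26,0.76,0.17,25.40,24.69,0.044
LS1A,Lutendele,39.77,3.16,3.04,338.41,1785.77,0.39,3.02,5.35,254.15,0.24,0.30,2.72,0.01,0.22,1.37,0.06,31.94,2.78,0.013
LS1M,Lutendele,28.95,1.85,2.11,293.70,1068.39,0.17,3.02,7.55,59.91,0.16,0.27,1.05,0.00,0.11,1.06,0.08,9.54,1.89,0.009
LS2A,Lutendele,6.35,1.06,1.47,289.62,741.50,0.18,3.02,7.87,153.28,0.12,0.21,1.99,0.01,0.14,1.02,0.06,11.87,1.22,0.011
LS2M,Lutendele,11.39,1.15,1.13,329.97,814.13,0.20,3.63,6.88,84.01,0.11,0.13,0.80,0.00,0.18,0.89,0.06,35.65,1.42,0.005
LS3A,Lutendele,35.82,4.38,3.61,488.09,2696.99,0.54,2.89,10.05,176.56,0.39,0.58,0.74,0.01,0.47,0.44,0.06,40.86,3.91,0.023
LS3M,Lutendele,18.62,2.28,2.20,236.75,1431.44,0.20,5.73,33.59,63.00,0.21,0.20,3.55,0.01,0.08,0.68,0.10,12.45,3.23,0.007
LS4A,Lutendele,8.40,1.98,1.89,968.05,1235.82,0.89,2.26,7.65,277.45,0.21,0.26,0.69,0.01,0.57,0.82,0.11,51.12,2.73,0.019
LS4M,Lutendele,15.16,1.77,1.65,361.68,1153.31,0.19,1.84,7.63,31.77,0.18,0.15,0.42,0.00,0.17,0.78,0.06,16.85,2.40,0.028
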