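species,sex,tissue,element,value,sd,n
sheep,female,muscle,Cd,ND,,20
sheep,male,muscle,Cd,ND,,20
goat,female,muscle,Cd,ND,,20
goat,male,muscle,Cd,ND,,20
sheep,female,liver,Cd,0.15,0.01,20
sheep,male,liver,Cd,0.12,0.01,20
goat,female,liver,Cd,0.081,0.01,20
goat,male,liver,Cd,0.14,0.01,20
sheep,female,muscle,Pb,ND,,20
sheep,male,muscle,Pb,ND,,20
goat,female,muscle,Pb,0.41,0.04,20
goat,male,muscle,Pb,0.23,0.01,20
sheep,female,liver,Pb,0.12,0.02,20
sheep,male,liver,Pb,0.57,0.02,20
goat,female,liver,Pb,0.65,0.02,20
goat,male,liver,Pb,0.29,0.01,20
sheep,female,muscle,Ni,0.83,0.07,20
sheep,male,muscle,Ni,0.84,0.06,20
goat,female,muscle,Ni,1.2,0.27,20
goat,male,muscle,Ni,0.76,0.02,20
sheep,female,liver,Ni,0.79,0.06,20
sheep,male,liver,Ni,0.84,0.07,20
goat,female,liver,Ni,0.83,0.05,20
goat,male,liver,Ni,0.78,0.03,20
sheep,female,muscle,Co,ND,,20
sheep,male,muscle,Co,ND,,20
goat,female,muscle,Co,ND,,20
goat,male,muscle,Co,ND,,20
sheep,female,liver,Co,0.070,0.03,20
sheep,male,liver,Co,0.084,0.03,20
goat,female,liver,Co,0.22,0.04,20
goat,male,liver,Co,0.31,0.09,20
sheep,female,muscle,Se,2.5,0.24,20
sheep,male,muscle,Se,2.0,0.07,20
goat,female,muscle,Se,2.0,0.18,20
goat,male,muscle,Se,2.0,0.06,20
sheep,female,liver,Se,2.7,0.22,20
sheep,male,liver,Se,2.0,0.09,20
goat,female,liver,Se,2.2,0.14,20
goat,male,liver,Se,2.2,0.09,20
sheep,female,muscle,Cu,9.6,0.029,20
sheep,male,muscle,Cu,9.4,0.33,20
goat,female,muscle,Cu,9.6,0.27,20
goat,male,muscle,Cu,9.4,0.28,20
sheep,female,liver,Cu,30,0.093,20
sheep,male,liver,Cu,32,0.63,20
goat,female,liver,Cu,34,0.64,20
goat,male,liver,Cu,36,0.62,20
sheep,female,muscle,Fe,112.7,3.84,20
sheep,male,muscle,Fe,113.3,1.79,20
goat,female,muscle,Fe,118.2,1.72,20
goat,male,muscle,Fe,115.3,1.11,20
sheep,female,liver,Fe,214.4,2.80,20
sheep,male,liver,Fe,233.0,1.45,20
goat,female,liver,Fe,225.7,2.63,20
goat,male,liver,Fe,226.7,0.98,20
sheep,female,muscle,Mg,717.3,36.60,20
sheep,male,muscle,Mg,865.7,22.30,20
goat,female,muscle,Mg,633.3,21.16,20
goat,male,muscle,Mg,356.8,17.97,20
sheep,female,liver,Mg,535.7,13.21,20
sheep,male,liver,Mg,546.6,17.24,20
goat,female,liver,Mg,614.4,4.35,20
goat,male,liver,Mg,458.6,17.49,20
sheep,female,muscle,Mn,0.71,0.14,20
sheep,male,muscle,Mn,1.8,0.10,20
goat,female,muscle,Mn,1.0,0.17,20
goat,male,muscle,Mn,0.98,0.10,20
sheep,female,liver,Mn,6.6,0.28,20
sheep,male,liver,Mn,8.1,0.10,20
goat,female,liver,Mn,6.0,0.39,20
goat,male,liver,Mn,5.1,0.41,20
sheep,female,muscle,Zn,102.9,5.10,20
sheep,male,muscle,Zn,106.1,2.30,20
goat,female,muscle,Zn,113.7,2.71,20
goat,male,muscle,Zn,113.0,1.04,20
sheep,female,liver,Zn,86.26,2.88,20
sheep,male,liver,Zn,132.5,0.87,20
goat,female,liver,Zn,96.53,0.92,20
goat,male,liver,Zn,75.33,0.46,20
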