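base,molecular_weight,density,refractive_index,melting_point,boiling_point,logP,dipole_moment,tpsa,pKaH
triethylamine,101.19,0.726,1.401,-114.7,89.0,1.45,0.66,3.2,10.75
DIPEA,129.24,0.742,1.414,-50.0,127.0,2.37,0.78,3.2,11.40
DBU,152.24,1.018,1.522,-70.0,261.0,1.10,3.10,15.6,12.00
aniline,93.13,1.022,1.586,-6.3,184.1,0.90,1.53,26.0,4.60
pyridine,79.10,0.982,1.510,-41.6,115.2,0.65,2.22,12.9,5.20
2-picoline,93.13,0.943,1.501,-66.7,128.2,1.11,1.85,12.9,5.97
2_6-lutidine,107.15,0.920,1.497,-6.1,144.0,1.68,1.66,12.9,6.60
2_4_6-collidine,121.18,0.917,1.498,-44.5,170.4,1.98,2.05,12.9,7.43
DMAP,122.17,1.010,1.560,113.0,211.0,1.20,4.30,16.1,9.70
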