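id,name,hemisphere,r,g,b
4,Left-Lateral-Ventricle,lh,120,18,134
5,Left-Inf-Lat-Vent,lh,196,58,250
10,Left-Thalamus-Proper,lh,0,118,14
11,Left-Caudate,lh,122,186,220
12,Left-Putamen,lh,236,13,176
13,Left-Pallidum,lh,12,48,255
14,Third-Ventricle,midline,204,182,142
15,Fourth-Ventricle,midline,42,204,164
16,Brain-Stem,midline,119,159,176
17,Left-Hippocampus,lh,220,216,20
18,Left-Amygdala,lh,103,255,255
26,Left-Accumbens-area,lh,255,165,0
28,Left-VentralDC,lh,165,42,42
43,Right-Lateral-Ventricle,rh,120,18,134
44,Right-Inf-Lat-Vent,rh,196,58,250
49,Right-Thalamus-Proper,rh,0,118,14
50,Right-Caudate,rh,122,186,220
51,Right-Putamen,rh,236,13,176
52,Right-Pallidum,rh,13,48,255
53,Right-Hippocampus,rh,220,216,20
54,Right-Amygdala,rh,103,255,255
58,Right-Accumbens-area,rh,255,165,0
60,Right-VentralDC,rh,165,42,42
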