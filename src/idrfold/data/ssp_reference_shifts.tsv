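# Random-coil 13Ca/13Cb chemical shifts (ppm) and full-structure secondary-shift
# constants per residue type, compiled from the random-coil and secondary-shift
# literature.  Editable: any table with these columns can be substituted.
# rc_* = random coil reference; helix_d* / strand_d* = secondary shift of the
# fully formed helix / strand (observed minus coil).  Glycine has no Cb.
aa	rc_ca	rc_cb	helix_dca	helix_dcb	strand_dca	strand_dcb
A	52.5	19.1	3.2	-0.5	-1.5	2.4
C	58.2	28.0	2.9	-0.6	-1.6	2.5
D	54.2	41.1	3.0	-0.4	-1.4	2.2
E	56.6	29.9	3.1	-0.5	-1.5	2.3
F	57.7	39.6	3.0	-0.7	-1.7	2.6
G	45.1	nan	2.4	nan	-1.2	nan
H	55.0	29.0	2.9	-0.5	-1.5	2.3
I	61.1	38.8	2.9	-0.8	-1.6	2.7
K	56.2	33.1	3.1	-0.5	-1.5	2.3
L	55.1	42.4	3.1	-0.6	-1.5	2.4
M	55.4	32.9	3.1	-0.6	-1.5	2.4
N	53.1	38.9	2.8	-0.4	-1.3	2.1
P	63.3	32.1	2.2	-0.4	-1.2	2.0
Q	55.7	29.4	3.1	-0.5	-1.5	2.3
R	56.0	30.9	3.1	-0.5	-1.5	2.3
S	58.3	63.8	2.8	-0.5	-1.4	2.2
T	61.8	69.8	2.8	-0.7	-1.4	2.5
V	62.2	32.9	2.9	-0.8	-1.6	2.7
W	57.5	29.6	2.9	-0.6	-1.6	2.4
Y	57.9	38.8	3.0	-0.7	-1.7	2.6
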