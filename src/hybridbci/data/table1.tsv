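participant	eeg	f_low	f_high	nirs	hyb
1	96.5	4.0	11.5	76.0	96.3
2	79.0	5.5	10.5	75.3	84.0
3	58.2	14.0	35.0	67.3	67.5
4	90.7	4.5	10.5	81.0	92.3
5	95.7	8.0	12.5	74.5	96.2
6	83.0	14.5	19.5	89.5	91.8
7	50.7	23.5	35.0	71.8	70.2
8	66.2	19.5	23.5	71.8	74.2
9	81.2	4.0	8.0	68.0	85.7
10	76.8	24.5	35.0	77.8	80.2
11	96.0	4.0	10.5	85.0	95.3
12	53.7	6.0	9.0	73.0	72.8
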