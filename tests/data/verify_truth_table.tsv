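n_a	n_b	concordant	paired_nondup	expected
0	0	yes	none	absent
0	0	yes	4	absent
0	0	yes	5	absent
0	0	no	none	absent
0	0	no	4	absent
0	0	no	5	absent
0	1	yes	none	equivocal
0	1	yes	4	equivocal
0	1	yes	5	equivocal
0	1	no	none	equivocal
0	1	no	4	equivocal
0	1	no	5	equivocal
0	2	yes	none	equivocal
0	2	yes	4	equivocal
0	2	yes	5	equivocal
0	2	no	none	equivocal
0	2	no	4	equivocal
0	2	no	5	equivocal
0	5	yes	none	equivocal
0	5	yes	4	equivocal
0	5	yes	5	equivocal
0	5	no	none	equivocal
0	5	no	4	equivocal
0	5	no	5	equivocal
1	0	yes	none	equivocal
1	0	yes	4	equivocal
1	0	yes	5	equivocal
1	0	no	none	equivocal
1	0	no	4	equivocal
1	0	no	5	equivocal
1	1	yes	none	equivocal
1	1	yes	4	equivocal
1	1	yes	5	confirmed
1	1	no	none	equivocal
1	1	no	4	equivocal
1	1	no	5	equivocal
1	2	yes	none	equivocal
1	2	yes	4	equivocal
1	2	yes	5	confirmed
1	2	no	none	equivocal
1	2	no	4	equivocal
1	2	no	5	equivocal
1	5	yes	none	equivocal
1	5	yes	4	equivocal
1	5	yes	5	confirmed
1	5	no	none	equivocal
1	5	no	4	equivocal
1	5	no	5	equivocal
2	0	yes	none	equivocal
2	0	yes	4	equivocal
2	0	yes	5	equivocal
2	0	no	none	equivocal
2	0	no	4	equivocal
2	0	no	5	equivocal
2	1	yes	none	equivocal
2	1	yes	4	equivocal
2	1	yes	5	confirmed
2	1	no	none	equivocal
2	1	no	4	equivocal
2	1	no	5	equivocal
2	2	yes	none	confirmed
2	2	yes	4	confirmed
2	2	yes	5	confirmed
2	2	no	none	equivocal
2	2	no	4	equivocal
2	2	no	5	equivocal
2	5	yes	none	confirmed
2	5	yes	4	confirmed
2	5	yes	5	confirmed
2	5	no	none	equivocal
2	5	no	4	equivocal
2	5	no	5	equivocal
5	0	yes	none	equivocal
5	0	yes	4	equivocal
5	0	yes	5	equivocal
5	0	no	none	equivocal
5	0	no	4	equivocal
5	0	no	5	equivocal
5	1	yes	none	equivocal
5	1	yes	4	equivocal
5	1	yes	5	confirmed
5	1	no	none	equivocal
5	1	no	4	equivocal
5	1	no	5	equivocal
5	2	yes	none	confirmed
5	2	yes	4	confirmed
5	2	yes	5	confirmed
5	2	no	none	equivocal
5	2	no	4	equivocal
5	2	no	5	equivocal
5	5	yes	none	confirmed
5	5	yes	4	confirmed
5	5	yes	5	confirmed
5	5	no	none	equivocal
5	5	no	4	equivocal
5	5	no	5	equivocal
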