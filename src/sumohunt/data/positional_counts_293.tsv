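residue	-10	-9	-8	-7	-6	-5	-4	-3	-2	-1	0	+1	+2	+3	+4	+5	+6	+7	+8	+9	+10
A	7	23	24	21	19	17	28	21	24	14	0	13	2	13	9	17	17	18	15	13	18
R	7	16	10	10	11	16	16	14	13	4	0	10	2	13	9	6	9	7	21	14	16
N	14	11	9	13	13	13	12	8	12	0	0	6	1	14	9	12	5	12	14	8	5
D	13	18	16	18	10	11	14	13	16	1	0	10	13	17	32	45	20	24	13	23	13
C	6	2	8	2	8	2	1	2	7	2	0	3	1	1	2	1	7	3	4	5	11
E	26	21	21	27	21	28	20	13	23	10	0	33	224	18	34	24	31	37	39	26	19
Q	10	13	13	17	22	15	19	12	21	3	0	43	2	13	13	13	8	13	12	17	20
G	17	17	17	14	14	16	14	15	22	4	0	4	6	18	14	12	14	12	12	13	12
H	11	8	10	5	7	5	7	7	3	1	0	4	1	4	6	6	6	7	10	8	6
I	11	14	8	2	19	10	9	14	11	92	0	8	3	9	12	6	6	11	10	9	10
L	28	22	24	30	18	30	29	22	24	45	0	20	5	22	26	26	18	22	28	21	27
K	24	19	12	21	21	20	19	32	31	10	293	21	9	25	28	15	20	16	10	22	16
M	14	5	11	7	3	4	10	5	4	6	0	14	2	6	7	7	8	8	3	4	2
F	8	4	7	12	10	8	6	6	6	9	0	6	5	9	4	13	12	9	7	7	6
P	26	18	30	33	29	29	27	33	14	6	0	14	7	54	24	17	40	23	15	22	23
S	23	30	21	28	28	29	29	29	24	6	0	21	4	20	21	37	25	30	27	30	34
T	18	16	15	11	16	21	17	15	14	5	0	32	3	11	14	14	20	10	10	9	14
W	3	2	4	2	0	0	1	3	1	0	0	3	0	1	0	4	1	3	0	2	2
Y	3	8	7	4	3	4	6	2	6	2	0	4	1	7	8	6	8	7	13	12	6
V	14	20	22	13	19	14	9	27	17	73	0	24	2	17	18	8	10	11	17	15	14
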