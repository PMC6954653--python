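chromosome	arm	band	parent	resolutions
1	p	36		300
1	p	35		300
1	p	34		300
1	p	33		300
1	p	32		300
1	p	31		300
1	p	22		300
1	p	21		300
1	p	13		300
1	p	12		300
1	p	11		300
1	q	11		300
1	q	12		300
1	q	21		300
1	q	22		300
1	q	23		300
1	q	24		300
1	q	25		300
1	q	31		300
1	q	32		300
1	q	41		300
1	q	42		300
1	q	43		300
1	q	44		300
2	p	25		300
2	p	24		300
2	p	23		300
2	p	22		300
2	p	21		300
2	p	16		300
2	p	15		300
2	p	14		300
2	p	13		300
2	p	12		300
2	p	11		300
2	q	11		300
2	q	12		300
2	q	13		300
2	q	14		300
2	q	21		300
2	q	22		300
2	q	23		300
2	q	24		300
2	q	31		300
2	q	32		300
2	q	33		300
2	q	34		300
2	q	35		300
2	q	36		300
2	q	37		300
3	p	26		300
3	p	25		300
3	p	24		300
3	p	23		300
3	p	22		300
3	p	21		300
3	p	14		300
3	p	13		300
3	p	12		300
3	p	11		300
3	q	11		300
3	q	12		300
3	q	13		300
3	q	21		300
3	q	22		300
3	q	23		300
3	q	24		300
3	q	25		300
3	q	26		300
3	q	27		300
3	q	28		300
3	q	29		300
4	p	16		300
4	p	15		300
4	p	14		300
4	p	13		300
4	p	12		300
4	p	11		300
4	q	11		300
4	q	12		300
4	q	13		300
4	q	21		300
4	q	22		300
4	q	23		300
4	q	24		300
4	q	25		300
4	q	26		300
4	q	27		300
4	q	28		300
4	q	31		300
4	q	32		300
4	q	33		300
4	q	34		300
4	q	35		300
5	p	15		300
5	p	14		300
5	p	13		300
5	p	12		300
5	p	11		300
5	q	11		300
5	q	12		300
5	q	13		300
5	q	14		300
5	q	15		300
5	q	21		300
5	q	22		300
5	q	23		300
5	q	31		300
5	q	32		300
5	q	33		300
5	q	34		300
5	q	35		300
6	p	25		300
6	p	24		300
6	p	23		300
6	p	22		300
6	p	21		300
6	p	12		300
6	p	11		300
6	q	11		300
6	q	12		300
6	q	13		300
6	q	14		300
6	q	15		300
6	q	16		300
6	q	21		300
6	q	22		300
6	q	23		300
6	q	24		300
6	q	25		300
6	q	26		300
6	q	27		300
7	p	22		300
7	p	21		300
7	p	15		300
7	p	14		300
7	p	13		300
7	p	12		300
7	p	11		300
7	q	11		300
7	q	21		300
7	q	22		300
7	q	31		300
7	q	32		300
7	q	33		300
7	q	34		300
7	q	35		300
7	q	36		300
8	p	23		300
8	p	22		300
8	p	21		300
8	p	12		300
8	p	11		300
8	q	11		300
8	q	12		300
8	q	13		300
8	q	21		300
8	q	22		300
8	q	23		300
8	q	24		300
9	p	24		300
9	p	23		300
9	p	22		300
9	p	21		300
9	p	13		300
9	p	12		300
9	p	11		300
9	q	11		300
9	q	12		300
9	q	13		300
9	q	21		300
9	q	22		300
9	q	31		300
9	q	32		300
9	q	33		300
9	q	34		300
10	p	15		300
10	p	14		300
10	p	13		300
10	p	12		300
10	p	11		300
10	q	11		300
10	q	21		300
10	q	22		300
10	q	23		300
10	q	24		300
10	q	25		300
10	q	26		300
11	p	15		300
11	p	14		300
11	p	13		300
11	p	12		300
11	p	11		300
11	q	11		300
11	q	12		300
11	q	13		300
11	q	14		300
11	q	21		300
11	q	22		300
11	q	23		300
11	q	24		300
11	q	25		300
12	p	13		300
12	p	12		300
12	p	11		300
12	q	11		300
12	q	12		300
12	q	13		300
12	q	14		300
12	q	15		300
12	q	21		300
12	q	22		300
12	q	23		300
12	q	24		300
13	p	13		300
13	p	12		300
13	p	11		300
13	q	11		300
13	q	12		300
13	q	13		300
13	q	14		300
13	q	21		300
13	q	22		300
13	q	31		300
13	q	32		300
13	q	33		300
13	q	34		300
14	p	13		300
14	p	12		300
14	p	11		300
14	q	11		300
14	q	12		300
14	q	13		300
14	q	21		300
14	q	22		300
14	q	23		300
14	q	24		300
14	q	31		300
14	q	32		300
15	p	13		300
15	p	12		300
15	p	11		300
15	q	11		300
15	q	12		300
15	q	13		300
15	q	14		300
15	q	15		300
15	q	21		300
15	q	22		300
15	q	23		300
15	q	24		300
15	q	25		300
15	q	26		300
16	p	13		300
16	p	12		300
16	p	11		300
16	q	11		300
16	q	12		300
16	q	13		300
16	q	21		300
16	q	22		300
16	q	23		300
16	q	24		300
17	p	13		300
17	p	12		300
17	p	11		300
17	q	11		300
17	q	12		300
17	q	21		300
17	q	21.1	21	550
17	q	21.2	21	550
17	q	21.31	21	550
17	q	21.32	21	550
17	q	21.33	21	550
17	q	22		300
17	q	23		300
17	q	24		300
17	q	25		300
18	p	11		300
18	q	11		300
18	q	12		300
18	q	21		300
18	q	22		300
18	q	23		300
19	p	13		300
19	p	12		300
19	p	11		300
19	q	11		300
19	q	12		300
19	q	13		300
20	p	13		300
20	p	12		300
20	p	11		300
20	q	11		300
20	q	12		300
20	q	13		300
21	p	13		300
21	p	12		300
21	p	11		300
21	q	11		300
21	q	21		300
21	q	22		300
22	p	13		300
22	p	12		300
22	p	11		300
22	q	11		300
22	q	12		300
22	q	13		300
X	p	22		300
X	p	21		300
X	p	11		300
X	q	11		300
X	q	12		300
X	q	13		300
X	q	21		300
X	q	22		300
X	q	23		300
X	q	24		300
X	q	25		300
X	q	26		300
X	q	27		300
X	q	28		300
Y	p	11		300
Y	q	11		300
Y	q	12		300
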