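patient	n_silenced	spared_positions
1	89	43
2	84	12 19 25 66 73 86
3	82	33 34 39 50 51 63 64 90
4	87	56 81 82
5	88	41 71
6	80	1 27 30 38 41 55 56 59 60 88
7	87	7 25 56
8	81	10 19 26 28 47 50 77 86 88
9	85	8 22 27 61 76
10	87	42 46 49
11	76	1 2 20 21 24 25 31 46 50 55 63 74 77 86
12	86	17 25 34 75
13	79	5 9 11 32 33 43 45 47 49 82 86
14	79	8 9 10 18 23 36 48 67 68 74 75
15	80	12 24 28 42 50 55 65 85 86 87
16	77	5 17 25 35 40 46 59 61 66 67 73 83 89
17	80	12 51 52 55 70 71 74 79 81 84
18	89	29
19	77	5 6 9 11 20 26 34 51 56 57 68 82 85
20	76	3 11 17 26 31 32 36 38 44 46 52 56 58 71
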