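node_id	network
1	DMN
2	DMN
3	DMN
4	DMN
5	DMN
6	DMN
7	DMN
8	DMN
9	DMN
10	DMN
11	DMN
12	DMN
13	DMN
14	DMN
15	DMN
16	DMN
17	DMN
18	DMN
19	DMN
20	DMN
21	DMN
22	DMN
23	DMN
24	DMN
25	DMN
26	DMN
27	DMN
28	DMN
29	DMN
30	DMN
31	DMN
32	DMN
33	DMN
34	DMN
35	DMN
36	DMN
37	DMN
38	DMN
39	DMN
40	DMN
41	DMN
42	DMN
43	DMN
44	DMN
45	DMN
46	DMN
47	DMN
48	DMN
49	DMN
50	DMN
51	DMN
52	DMN
53	DMN
54	DMN
55	DMN
56	DMN
57	DMN
58	DMN
59	VIS
60	VIS
61	VIS
62	VIS
63	VIS
64	VIS
65	VIS
66	VIS
67	VIS
68	VIS
69	VIS
70	VIS
71	VIS
72	VIS
73	VIS
74	VIS
75	VIS
76	VIS
77	VIS
78	VIS
79	VIS
80	VIS
81	VIS
82	VIS
83	VIS
84	VIS
85	VIS
86	VIS
87	VIS
88	VIS
89	VIS
90	SMN
91	SMN
92	SMN
93	SMN
94	SMN
95	SMN
96	SMN
97	SMN
98	SMN
99	SMN
100	SMN
101	SMN
102	SMN
103	SMN
104	SMN
105	SMN
106	SMN
107	SMN
108	SMN
109	SMN
110	SMN
111	SMN
112	SMN
113	SMN
114	SMN
115	SMN
116	SMN
117	SMN
118	SMN
119	SMN
120	SMN
121	SMN
122	SMN
123	SMN
124	SMN
125	FPN
126	FPN
127	FPN
128	FPN
129	FPN
130	FPN
131	FPN
132	FPN
133	FPN
134	FPN
135	FPN
136	FPN
137	FPN
138	FPN
139	FPN
140	FPN
141	FPN
142	FPN
143	FPN
144	FPN
145	FPN
146	FPN
147	FPN
148	FPN
149	FPN
150	SAN
151	SAN
152	SAN
153	SAN
154	SAN
155	SAN
156	SAN
157	SAN
158	SAN
159	SAN
160	SAN
161	SAN
162	SAN
163	SAN
164	SAN
165	SAN
166	SAN
167	SAN
168	CON
169	CON
170	CON
171	CON
172	CON
173	CON
174	CON
175	CON
176	CON
177	CON
178	CON
179	CON
180	CON
181	CON
182	AUD
183	AUD
184	AUD
185	AUD
186	AUD
187	AUD
188	AUD
189	AUD
190	AUD
191	AUD
192	AUD
193	AUD
194	AUD
195	SUB
196	SUB
197	SUB
198	SUB
199	SUB
200	SUB
201	SUB
202	SUB
203	SUB
204	SUB
205	SUB
206	SUB
207	SUB
208	VAN
209	VAN
210	VAN
211	VAN
212	VAN
213	VAN
214	VAN
215	VAN
216	VAN
217	DAN
218	DAN
219	DAN
220	DAN
221	DAN
222	DAN
223	DAN
224	DAN
225	DAN
226	DAN
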