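roi_id	network
1	Default
2	Default
3	Default
4	Default
5	Default
6	Default
7	Default
8	Default
9	Default
10	Default
11	Default
12	Default
13	Default
14	Default
15	Default
16	Default
17	Default
18	Default
19	Default
20	Default
21	Default
22	Default
23	Default
24	Default
25	Default
26	Default
27	Default
28	Default
29	Default
30	Default
31	Default
32	Default
33	Default
34	Default
35	Default
36	Default
37	Default
38	Default
39	Default
40	Default
41	Default
42	SMhand
43	SMhand
44	SMhand
45	SMhand
46	SMhand
47	SMhand
48	SMhand
49	SMhand
50	SMhand
51	SMhand
52	SMhand
53	SMhand
54	SMhand
55	SMhand
56	SMhand
57	SMhand
58	SMhand
59	SMhand
60	SMhand
61	SMhand
62	SMhand
63	SMhand
64	SMhand
65	SMhand
66	SMhand
67	SMhand
68	SMhand
69	SMhand
70	SMhand
71	SMhand
72	SMhand
73	SMhand
74	SMhand
75	SMhand
76	SMhand
77	SMhand
78	SMhand
79	SMhand
80	SMmouth
81	SMmouth
82	SMmouth
83	SMmouth
84	SMmouth
85	SMmouth
86	SMmouth
87	SMmouth
88	Visual
89	Visual
90	Visual
91	Visual
92	Visual
93	Visual
94	Visual
95	Visual
96	Visual
97	Visual
98	Visual
99	Visual
100	Visual
101	Visual
102	Visual
103	Visual
104	Visual
105	Visual
106	Visual
107	Visual
108	Visual
109	Visual
110	Visual
111	Visual
112	Visual
113	Visual
114	Visual
115	Visual
116	Visual
117	Visual
118	Visual
119	Visual
120	Visual
121	Visual
122	Visual
123	Visual
124	Visual
125	Visual
126	Visual
127	FrontoParietal
128	FrontoParietal
129	FrontoParietal
130	FrontoParietal
131	FrontoParietal
132	FrontoParietal
133	FrontoParietal
134	FrontoParietal
135	FrontoParietal
136	FrontoParietal
137	FrontoParietal
138	FrontoParietal
139	FrontoParietal
140	FrontoParietal
141	FrontoParietal
142	FrontoParietal
143	FrontoParietal
144	FrontoParietal
145	FrontoParietal
146	FrontoParietal
147	FrontoParietal
148	FrontoParietal
149	FrontoParietal
150	FrontoParietal
151	Auditory
152	Auditory
153	Auditory
154	Auditory
155	Auditory
156	Auditory
157	Auditory
158	Auditory
159	Auditory
160	Auditory
161	Auditory
162	Auditory
163	Auditory
164	Auditory
165	Auditory
166	Auditory
167	Auditory
168	Auditory
169	Auditory
170	Auditory
171	Auditory
172	Auditory
173	Auditory
174	Auditory
175	CinguloParietal
176	CinguloParietal
177	CinguloParietal
178	CinguloParietal
179	CinguloParietal
180	RetrosplenialTemporal
181	RetrosplenialTemporal
182	RetrosplenialTemporal
183	RetrosplenialTemporal
184	RetrosplenialTemporal
185	RetrosplenialTemporal
186	RetrosplenialTemporal
187	RetrosplenialTemporal
188	CinguloOperc
189	CinguloOperc
190	CinguloOperc
191	CinguloOperc
192	CinguloOperc
193	CinguloOperc
194	CinguloOperc
195	CinguloOperc
196	CinguloOperc
197	CinguloOperc
198	CinguloOperc
199	CinguloOperc
200	CinguloOperc
201	CinguloOperc
202	CinguloOperc
203	CinguloOperc
204	CinguloOperc
205	CinguloOperc
206	CinguloOperc
207	CinguloOperc
208	CinguloOperc
209	CinguloOperc
210	CinguloOperc
211	CinguloOperc
212	CinguloOperc
213	CinguloOperc
214	CinguloOperc
215	CinguloOperc
216	CinguloOperc
217	CinguloOperc
218	CinguloOperc
219	CinguloOperc
220	CinguloOperc
221	CinguloOperc
222	CinguloOperc
223	CinguloOperc
224	CinguloOperc
225	CinguloOperc
226	CinguloOperc
227	CinguloOperc
228	VentralAttn
229	VentralAttn
230	VentralAttn
231	VentralAttn
232	VentralAttn
233	VentralAttn
234	VentralAttn
235	VentralAttn
236	VentralAttn
237	VentralAttn
238	VentralAttn
239	VentralAttn
240	VentralAttn
241	VentralAttn
242	VentralAttn
243	VentralAttn
244	VentralAttn
245	VentralAttn
246	VentralAttn
247	VentralAttn
248	VentralAttn
249	VentralAttn
250	VentralAttn
251	Salience
252	Salience
253	Salience
254	Salience
255	DorsalAttn
256	DorsalAttn
257	DorsalAttn
258	DorsalAttn
259	DorsalAttn
260	DorsalAttn
261	DorsalAttn
262	DorsalAttn
263	DorsalAttn
264	DorsalAttn
265	DorsalAttn
266	DorsalAttn
267	DorsalAttn
268	DorsalAttn
269	DorsalAttn
270	DorsalAttn
271	DorsalAttn
272	DorsalAttn
273	DorsalAttn
274	DorsalAttn
275	DorsalAttn
276	DorsalAttn
277	DorsalAttn
278	DorsalAttn
279	DorsalAttn
280	DorsalAttn
281	DorsalAttn
282	DorsalAttn
283	DorsalAttn
284	DorsalAttn
285	DorsalAttn
286	DorsalAttn
287	None
288	None
289	None
290	None
291	None
292	None
293	None
294	None
295	None
296	None
297	None
298	None
299	None
300	None
301	None
302	None
303	None
304	None
305	None
306	None
307	None
308	None
309	None
310	None
311	None
312	None
313	None
314	None
315	None
316	None
317	None
318	None
319	None
320	None
321	None
322	None
323	None
324	None
325	None
326	None
327	None
328	None
329	None
330	None
331	None
332	None
333	None
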