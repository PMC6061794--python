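channel	row	col
1	0	0
2	1	0
3	2	0
4	3	0
5	0	1
6	1	1
7	2	1
8	3	1
9	0	2
10	1	2
11	2	2
12	3	2
13	0	3
14	1	3
15	2	3
16	3	3
17	0	4
18	1	4
19	2	4
20	3	4
21	0	5
22	1	5
23	2	5
24	3	5
25	0	6
26	1	6
27	2	6
28	3	6
29	0	7
30	1	7
31	2	7
32	3	7
33	0	8
34	1	8
35	2	8
36	3	8
37	0	9
38	1	9
39	2	9
40	3	9
41	0	10
42	1	10
43	2	10
44	3	10
45	0	11
46	1	11
47	2	11
48	3	11
49	0	12
50	1	12
51	2	12
52	3	12
53	0	13
54	1	13
55	2	13
56	3	13
57	0	14
58	1	14
59	2	14
60	3	14
61	0	15
62	1	15
63	2	15
64	3	15
65	0	16
66	1	16
67	2	16
68	3	16
69	0	17
70	1	17
71	2	17
72	3	17
73	0	18
74	1	18
75	2	18
76	3	18
77	0	19
78	1	19
79	2	19
80	3	19
81	0	20
82	1	20
83	2	20
84	3	20
85	0	21
86	1	21
87	2	21
88	3	21
89	0	22
90	1	22
91	2	22
92	3	22
93	0	23
94	1	23
95	2	23
96	3	23
97	0	24
98	1	24
99	2	24
100	3	24
101	0	25
102	1	25
103	2	25
104	3	25
105	0	26
106	1	26
107	2	26
108	3	26
109	0	27
110	1	27
111	2	27
112	3	27
113	0	28
114	1	28
115	2	28
116	3	28
117	0	29
118	1	29
119	2	29
120	3	29
121	0	30
122	1	30
123	2	30
124	3	30
125	0	31
126	1	31
127	2	31
128	3	31
129	4	0
130	5	0
131	6	0
132	7	0
133	4	1
134	5	1
135	6	1
136	7	1
137	4	2
138	5	2
139	6	2
140	7	2
141	4	3
142	5	3
143	6	3
144	7	3
145	4	4
146	5	4
147	6	4
148	7	4
149	4	5
150	5	5
151	6	5
152	7	5
153	4	6
154	5	6
155	6	6
156	7	6
157	4	7
158	5	7
159	6	7
160	7	7
161	4	8
162	5	8
163	6	8
164	7	8
165	4	9
166	5	9
167	6	9
168	7	9
169	4	10
170	5	10
171	6	10
172	7	10
173	4	11
174	5	11
175	6	11
176	7	11
177	4	12
178	5	12
179	6	12
180	7	12
181	4	13
182	5	13
183	6	13
184	7	13
185	4	14
186	5	14
187	6	14
188	7	14
189	4	15
190	5	15
191	6	15
192	7	15
193	4	16
194	5	16
195	6	16
196	7	16
197	4	17
198	5	17
199	6	17
200	7	17
201	4	18
202	5	18
203	6	18
204	7	18
205	4	19
206	5	19
207	6	19
208	7	19
209	4	20
210	5	20
211	6	20
212	7	20
213	4	21
214	5	21
215	6	21
216	7	21
217	4	22
218	5	22
219	6	22
220	7	22
221	4	23
222	5	23
223	6	23
224	7	23
225	4	24
226	5	24
227	6	24
228	7	24
229	4	25
230	5	25
231	6	25
232	7	25
233	4	26
234	5	26
235	6	26
236	7	26
237	4	27
238	5	27
239	6	27
240	7	27
241	4	28
242	5	28
243	6	28
244	7	28
245	4	29
246	5	29
247	6	29
248	7	29
249	4	30
250	5	30
251	6	30
252	7	30
253	4	31
254	5	31
255	6	31
256	7	31
257	8	0
258	9	0
259	10	0
260	11	0
261	8	1
262	9	1
263	10	1
264	11	1
265	8	2
266	9	2
267	10	2
268	11	2
269	8	3
270	9	3
271	10	3
272	11	3
273	8	4
274	9	4
275	10	4
276	11	4
277	8	5
278	9	5
279	10	5
280	11	5
281	8	6
282	9	6
283	10	6
284	11	6
285	8	7
286	9	7
287	10	7
288	11	7
289	8	8
290	9	8
291	10	8
292	11	8
293	8	9
294	9	9
295	10	9
296	11	9
297	8	10
298	9	10
299	10	10
300	11	10
301	8	11
302	9	11
303	10	11
304	11	11
305	8	12
306	9	12
307	10	12
308	11	12
309	8	13
310	9	13
311	10	13
312	11	13
313	8	14
314	9	14
315	10	14
316	11	14
317	8	15
318	9	15
319	10	15
320	11	15
321	8	16
322	9	16
323	10	16
324	11	16
325	8	17
326	9	17
327	10	17
328	11	17
329	8	18
330	9	18
331	10	18
332	11	18
333	8	19
334	9	19
335	10	19
336	11	19
337	8	20
338	9	20
339	10	20
340	11	20
341	8	21
342	9	21
343	10	21
344	11	21
345	8	22
346	9	22
347	10	22
348	11	22
349	8	23
350	9	23
351	10	23
352	11	23
353	8	24
354	9	24
355	10	24
356	11	24
357	8	25
358	9	25
359	10	25
360	11	25
361	8	26
362	9	26
363	10	26
364	11	26
365	8	27
366	9	27
367	10	27
368	11	27
369	8	28
370	9	28
371	10	28
372	11	28
373	8	29
374	9	29
375	10	29
376	11	29
377	8	30
378	9	30
379	10	30
380	11	30
381	8	31
382	9	31
383	10	31
384	11	31
385	12	0
386	13	0
387	14	0
388	15	0
389	12	1
390	13	1
391	14	1
392	15	1
393	12	2
394	13	2
395	14	2
396	15	2
397	12	3
398	13	3
399	14	3
400	15	3
401	12	4
402	13	4
403	14	4
404	15	4
405	12	5
406	13	5
407	14	5
408	15	5
409	12	6
410	13	6
411	14	6
412	15	6
413	12	7
414	13	7
415	14	7
416	15	7
417	12	8
418	13	8
419	14	8
420	15	8
421	12	9
422	13	9
423	14	9
424	15	9
425	12	10
426	13	10
427	14	10
428	15	10
429	12	11
430	13	11
431	14	11
432	15	11
433	12	12
434	13	12
435	14	12
436	15	12
437	12	13
438	13	13
439	14	13
440	15	13
441	12	14
442	13	14
443	14	14
444	15	14
445	12	15
446	13	15
447	14	15
448	15	15
449	12	16
450	13	16
451	14	16
452	15	16
453	12	17
454	13	17
455	14	17
456	15	17
457	12	18
458	13	18
459	14	18
460	15	18
461	12	19
462	13	19
463	14	19
464	15	19
465	12	20
466	13	20
467	14	20
468	15	20
469	12	21
470	13	21
471	14	21
472	15	21
473	12	22
474	13	22
475	14	22
476	15	22
477	12	23
478	13	23
479	14	23
480	15	23
481	12	24
482	13	24
483	14	24
484	15	24
485	12	25
486	13	25
487	14	25
488	15	25
489	12	26
490	13	26
491	14	26
492	15	26
493	12	27
494	13	27
495	14	27
496	15	27
497	12	28
498	13	28
499	14	28
500	15	28
501	12	29
502	13	29
503	14	29
504	15	29
505	12	30
506	13	30
507	14	30
508	15	30
509	12	31
510	13	31
511	14	31
512	15	31
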