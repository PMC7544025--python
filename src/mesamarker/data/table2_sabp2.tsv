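pos	ale_1	ale_2	ale_3	ale_4	ale_5	ale_6	len_1	len_2	len_3	len_4	len_5	len_6	bg_1	bg_2	bg_3	bg_4	med_1	med_2	med_3	med_4	pen_1	pen_2	pen_3	pen_4	pen_5	pen_6	uti_1	uti_2	uti_3	uti_4	nan_1	nan_2	nan_3	nan_4	aln_1	aln_2	aln_3	aln_4
160	S	S	S	S	S	S	C	C	C	C	S	S	S	S	S	S	S	S	S	S	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
189	R	R	R	R	R	R	A	A	A	A	A	R	R	R	R	R	R	R	R	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
262	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	W	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
298	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	A	G	G	R	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A
304	G	G	G	G	G	K	K	K	K	K	K	K	G	G	G	G	K	K	K	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T	T
336	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	A	R	R	R	R	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G	G
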