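# Ballesteros-Weinstein positions for the human AT1 receptor (AGTR1),
# GPCRdb generic numbering. Anchors: D74=2.50, R126=3.50 (DRY), K199=5.42,
# W253=6.48, P299=7.50 (NPxxY).
# position	chain:resnum
2.41	A:65
3.50	A:126
5.55	A:212
6.34	A:239
6.47	A:252
7.46	A:295
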