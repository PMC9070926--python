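# Default ribosome-binding-site weight matrix, consensus tvaGGag (v = A/C/G).
# Columns: position index, then weights for A, C, G, T.  Any matrix of the
# same shape may be substituted via --matrix.
position	A	C	G	T
0	0.0	0.0	0.0	0.5
1	0.2	0.2	0.2	0.0
2	0.3	0.0	0.0	0.0
3	0.0	0.0	0.9	0.0
4	0.0	0.0	0.9	0.0
5	0.2	0.0	0.1	0.0
6	0.1	0.0	0.4	0.0
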