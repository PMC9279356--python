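# LCPO coefficient table keyed by element and heavy-neighbour count.
# n_bonds = -1 matches any neighbour count for that element.
# Rows cover the common protein heavy-atom classes; atoms that match no row
# fall back to the generic first-order row (p1=1, p2=-1, p3=p4=0) in code.
element	n_bonds	radius	p1	p2	p3	p4
C	1	1.70	0.77887	-0.28063	-0.0012968	0.00039328
C	2	1.70	0.56482	-0.19608	-0.0010219	0.0002658
C	3	1.70	0.23348	-0.072627	-0.00020079	0.00007967
C	4	1.70	0.00000	0.00000	0.00000	0.00000
N	1	1.65	0.78602	-0.29198	-0.0006537	0.00036247
N	2	1.65	0.73511	-0.22116	-0.00089148	0.0002523
N	3	1.65	0.051481	-0.012603	-0.00032006	0.000024774
O	1	1.60	0.68563	-0.18680	-0.0013557	0.00023743
O	2	1.60	0.49392	-0.16038	-0.0015512	0.00016453
S	1	1.90	0.54581	-0.19477	-0.0012873	0.00029247
S	2	1.90	0.42951	-0.17431	-0.0004471	0.00019721
P	-1	1.90	0.03873	-0.0089339	0.0000083582	0.0000030381
F	-1	1.47	0.68563	-0.18680	-0.0013557	0.00023743
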