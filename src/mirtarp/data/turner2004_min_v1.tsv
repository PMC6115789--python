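# Nearest-neighbor RNA free-energy increments, delta-G at 37 C, kcal/mol.
# Parameter set id: turner2004-min, version 1.
# Turner-lab 2004-style increments rounded to 0.1 kcal/mol; simplified model:
# no sequence-dependent terminal mismatches, dangling ends or coaxial stacks;
# small internal loops use the generic size-based initiation table.
# Record schema (tab-separated):
#   stack <5'ac3'> <3'bd5'>  dG   : helix stack, pair a:b followed by pair c:d
#   hairpin|bulge|internal <size> dG : loop initiation by number of unpaired nt
#   ninio per_nt|max dG           : internal-loop asymmetry term
#   multibranch offset|per_branch|per_unpaired dG : linear multiloop model
#   init duplex dG                : intermolecular initiation
#   penalty terminal_au dG        : per helix end closed by AU/UA/GU/UG
#   extrapolation lxc dG          : loops beyond the table: dG(n)=dG(nmax)+lxc*ln(n/nmax)
#   limit max_loop|min_hairpin n  : structural limits
stack	CC	GG	-3.30
stack	CG	GC	-2.40
stack	CG	GU	-1.40
stack	CU	GG	-2.10
stack	CA	GU	-2.10
stack	CU	GA	-2.10
stack	GC	CG	-3.40
stack	GG	CC	-3.30
stack	GG	CU	-1.50
stack	GU	CG	-2.50
stack	GA	CU	-2.40
stack	GU	CA	-2.20
stack	GC	UG	-2.50
stack	GG	UC	-2.10
stack	GG	UU	-0.50
stack	GU	UG	1.30
stack	GA	UU	-1.30
stack	GU	UA	-1.40
stack	UC	GG	-1.50
stack	UG	GC	-1.40
stack	UG	GU	0.30
stack	UU	GG	-0.50
stack	UA	GU	-1.00
stack	UU	GA	-0.60
stack	AC	UG	-2.20
stack	AG	UC	-2.10
stack	AG	UU	-0.60
stack	AU	UG	-1.40
stack	AA	UU	-0.90
stack	AU	UA	-1.10
stack	UC	AG	-2.40
stack	UG	AC	-2.10
stack	UG	AU	-1.00
stack	UU	AG	-1.30
stack	UA	AU	-1.30
stack	UU	AA	-0.90
hairpin	3	5.40
hairpin	4	5.60
hairpin	5	5.70
hairpin	6	5.40
hairpin	7	6.00
hairpin	8	5.50
hairpin	9	6.40
hairpin	10	6.50
hairpin	11	6.60
hairpin	12	6.70
hairpin	13	6.80
hairpin	14	6.90
hairpin	15	6.90
hairpin	16	7.00
hairpin	17	7.10
hairpin	18	7.10
hairpin	19	7.20
hairpin	20	7.20
hairpin	21	7.30
hairpin	22	7.30
hairpin	23	7.40
hairpin	24	7.40
hairpin	25	7.50
hairpin	26	7.50
hairpin	27	7.50
hairpin	28	7.60
hairpin	29	7.60
hairpin	30	7.70
bulge	1	3.80
bulge	2	2.80
bulge	3	3.20
bulge	4	3.60
bulge	5	4.00
bulge	6	4.40
bulge	7	4.60
bulge	8	4.70
bulge	9	4.80
bulge	10	4.90
bulge	11	5.00
bulge	12	5.10
bulge	13	5.20
bulge	14	5.30
bulge	15	5.40
bulge	16	5.40
bulge	17	5.50
bulge	18	5.50
bulge	19	5.60
bulge	20	5.70
bulge	21	5.70
bulge	22	5.80
bulge	23	5.80
bulge	24	5.80
bulge	25	5.90
bulge	26	5.90
bulge	27	6.00
bulge	28	6.00
bulge	29	6.00
bulge	30	6.10
internal	2	1.00
internal	3	1.00
internal	4	1.10
internal	5	2.00
internal	6	2.00
internal	7	2.10
internal	8	2.30
internal	9	2.40
internal	10	2.50
internal	11	2.60
internal	12	2.70
internal	13	2.80
internal	14	2.90
internal	15	2.90
internal	16	3.00
internal	17	3.10
internal	18	3.10
internal	19	3.20
internal	20	3.30
internal	21	3.30
internal	22	3.40
internal	23	3.40
internal	24	3.50
internal	25	3.50
internal	26	3.50
internal	27	3.60
internal	28	3.60
internal	29	3.70
internal	30	3.70
ninio	per_nt	0.60
ninio	max	3.00
multibranch	offset	9.30
multibranch	per_branch	-0.90
multibranch	per_unpaired	0.00
init	duplex	4.10
penalty	terminal_au	0.50
extrapolation	lxc	1.08
limit	max_loop	30
limit	min_hairpin	3
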