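# TRX dinucleotide flexibility scale: percentage of time a phosphate
# linkage spends in the BII backbone conformation, measured in free
# solution.  One row per strand-symmetric dinucleotide class; a class
# contains a dimer and its reverse complement (palindromic dimers form
# singleton classes).  Scores run from 0 (stiff, e.g. ApT) to 43
# (flexible, CpG) and rise with GC content.  ApT and ApA/TpT share the
# minimum score, so the 10 classes collapse to 9 distinct linkage states.
# Columns: class <TAB> dimers (comma-separated) <TAB> score
AT	AT	0
AA	AA,TT	0
AG	AG,CT	5
GA	GA,TC	9
AC	AC,GT	10
TA	TA	13
GG	GG,CC	23
CA	CA,TG	25
GC	GC	40
CG	CG	43
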