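Mutant ID	Start chrom	Start pos	End chrom	End pos	Type	Note	Imprecise
AG4	ChrI	183236	ChrIV	964883	Translocation		0
AG4	ChrI	183237	ChrI	2609500	Deletion	Around rDNA	1
AG4	ChrII	725780	ChrII	1407626	Deletion		0
AG4	ChrII	1305106	ChrII	1546790	Deletion		0
AG9	ChrI	3209917	ChrI	3216299	Deletion		0
AG9	ChrIII	1869226	ChrIII	1936358	Deletion		0
AG9	ChrIII		ChrIII		Aneuploidy	Whole chromosome III	0
AG9	ChrI	2613000	ChrI	3209916	Partial duplication	Around rDNA	1
AG4	ChrI	4357880	ChrI	4541153	Break induced repair		0
AG4	ChrIV	1	ChrIV	463762	Break induced repair		0
AG9	ChrIII	1705647	ChrIII	2119607	Break induced repair		0
AG4	ChrI	249379	ChrI	398066	Gene conversion		0
AG4	ChrI	3814598	ChrI	3819195	Gene conversion		0
AG4	ChrII	751384	ChrII	920699	Gene conversion		0
AG4	ChrII	938020	ChrII	1317635	Gene conversion		0
AG4	ChrII	1318690	ChrII	1415237	Gene conversion		0
AG4	ChrII	1567821	ChrII	1572073	Gene conversion		0
AG4	ChrII	1581636	ChrII	1583219	Gene conversion		0
AG4	ChrIV	671337	ChrIV	673840	Gene conversion		0
AG4	ChrIV	730060	ChrIV	731830	Gene conversion		0
AG9	ChrI	408842	ChrI	409294	Gene conversion		0
AG9	ChrI	409925	ChrI	2084873	Gene conversion	Around rDNA	1
AG9	ChrI	409925	ChrI	2084873	Gene conversion	Around rDNA	1
AG9	ChrIII	1920323	ChrIII	1933957	Gene conversion		0
AG9	ChrIII	1934656	ChrIII	1936316	Gene conversion		0
AG4	ChrII	681967	ChrII		SNV	G>T	0
AG4	ChrIII	1600622	ChrIII		SNV	ACTT>GTA	0
AG9	ChrIII	1496570	ChrIII		SNV	G>A	0
AG9	ChrIV	1409750	ChrIV		SNV	G>A	0
AG4	ChrIV	904210	ChrIV		InDel	G>GA,GC	0
AG9	ChrIII	1496562	ChrIII	1496566	InDel	GCCTC>G	0
AG9	ChrIII	1496572	ChrIII		InDel	T>TAT	0
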