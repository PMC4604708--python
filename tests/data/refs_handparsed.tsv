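raw	surname	year	source	volume	page	doi
SMITH J, 2001, J CLIN ONCOL, V19, P1001, DOI 10.1000/xyz	SMITH J	2001	J CLIN ONCOL	19	1001	10.1000/xyz
ANONYMOUS, 1919, NY MED J	ANONYMOUS	1919	NY MED J
JONES PR, 1998, LANCET, V352, P837	JONES PR	1998	LANCET	352	837
BROWN KL, 2005, NEW ENGL J MED, V353, P2643, DOI 10.1056/NEJMoa052187	BROWN KL	2005	NEW ENGL J MED	353	2643	10.1056/nejmoa052187
WHO, 2010, WHO TECHN REP SER	WHO	2010	WHO TECHN REP SER
GARCIA M, 1969, PRESSE MED, V77, P123	GARCIA M	1969	PRESSE MED	77	123
OKEEFE SJ, 2010, AM J GASTROENTEROL, V105, P2350, DOI 10.1038/ajg.2010.253	OKEEFE SJ	2010	AM J GASTROENTEROL	105	2350	10.1038/ajg.2010.253
LI X, 2014, PLOS ONE, V9, DOI 10.1371/journal.pone.0099682	LI X	2014	PLOS ONE	9		10.1371/journal.pone.0099682
NAKAMURA T, 1995, CIRCULATION, V92, P1954	NAKAMURA T	1995	CIRCULATION	92	1954
MULLER H, 1974, DEUT MED WOCHENSCHR, V99, P2261	MULLER H	1974	DEUT MED WOCHENSCHR	99	2261
TAYLOR R, 2013, COCHRANE DB SYST REV, DOI 10.1002/14651858.CD004816.pub5	TAYLOR R	2013	COCHRANE DB SYST REV			10.1002/14651858.cd004816.pub5
EVANS A, CANCER RES, V55, P3752	EVANS A		CANCER RES	55	3752
PETROV V, 1981, VOPR ONKOL, V27, P28	PETROV V	1981	VOPR ONKOL	27	28
VANDENBERG P, 2000, J BONE MINER RES, V15, P710	VANDENBERG P	2000	J BONE MINER RES	15	710
CHEN Y, 2015, BMJ-BRIT MED J, V350, DOI 10.1136/bmj.h1354	CHEN Y	2015	BMJ-BRIT MED J	350		10.1136/bmj.h1354
DUBOIS R, 1955, AM REV TUBERC, V71, P50	DUBOIS R	1955	AM REV TUBERC	71	50
KIM SH, 2012, INT J EPIDEMIOL, V41, P1187, DOI 10.1093/ije/dys100	KIM SH	2012	INT J EPIDEMIOL	41	1187	10.1093/ije/dys100
ROSSI E, 1990, MINERVA MED, V81, P533	ROSSI E	1990	MINERVA MED	81	533
ANDERSON JL, 2007, CIRCULATION, V116, PE148	ANDERSON JL	2007	CIRCULATION	116	E148
IVANOV I, 2003, TER ARKH, V75, P30	IVANOV I	2003	TER ARKH	75	30
SILVA AB, 2011, REV SAUDE PUBL, V45, P1	SILVA AB	2011	REV SAUDE PUBL	45	1
THOMPSON SG, 1999, STAT MED, V18, P2693	THOMPSON SG	1999	STAT MED	18	2693
HIGGINS JPT, 2003, BMJ-BRIT MED J, V327, P557, DOI 10.1136/bmj.327.7414.557	HIGGINS JPT	2003	BMJ-BRIT MED J	327	557	10.1136/bmj.327.7414.557
DERSIMONIAN R, 1986, CONTROL CLIN TRIALS, V7, P177	DERSIMONIAN R	1986	CONTROL CLIN TRIALS	7	177
EGGER M, 1997, BMJ-BRIT MED J, V315, P629	EGGER M	1997	BMJ-BRIT MED J	315	629
BEGG CB, 1994, BIOMETRICS, V50, P1088	BEGG CB	1994	BIOMETRICS	50	1088
MANTEL N, 1959, J NATL CANCER I, V22, P719	MANTEL N	1959	J NATL CANCER I	22	719
PETO R, 1976, BRIT J CANCER, V34, P585	PETO R	1976	BRIT J CANCER	34	585
YUSUF S, 1985, PROG CARDIOVASC DIS, V27, P335	YUSUF S	1985	PROG CARDIOVASC DIS	27	335
COCHRAN WG, 1954, BIOMETRICS, V10, P101	COCHRAN WG	1954	BIOMETRICS	10	101
LAU J, 1992, NEW ENGL J MED, V327, P248	LAU J	1992	NEW ENGL J MED	327	248
MOHER D, 2009, PLOS MED, V6, DOI 10.1371/journal.pmed.1000097	MOHER D	2009	PLOS MED	6		10.1371/journal.pmed.1000097
STROUP DF, 2000, JAMA-J AM MED ASSOC, V283, P2008	STROUP DF	2000	JAMA-J AM MED ASSOC	283	2008
LIBERATI A, 2009, ANN INTERN MED, V151, PW65	LIBERATI A	2009	ANN INTERN MED	151	W65
WELLS GA, 2011, NEWCASTLE OTTAWA SCA	WELLS GA	2011	NEWCASTLE OTTAWA SCA
SCHULZ KF, 1995, JAMA-J AM MED ASSOC, V273, P408	SCHULZ KF	1995	JAMA-J AM MED ASSOC	273	408
JADAD AR, 1996, CONTROL CLIN TRIALS, V17, P1	JADAD AR	1996	CONTROL CLIN TRIALS	17	1
HOZO SP, 2005, BMC MED RES METHODOL, V5, DOI 10.1186/1471-2288-5-13	HOZO SP	2005	BMC MED RES METHODOL	5		10.1186/1471-2288-5-13
FOLLMANN D, 1992, J CLIN EPIDEMIOL, V45, P769	FOLLMANN D	1992	J CLIN EPIDEMIOL	45	769
HEDGES LV, 1985, STAT METHODS METAANA	HEDGES LV	1985	STAT METHODS METAANA
STERNE JAC, 2011, BMJ-BRIT MED J, V343, DOI 10.1136/bmj.d4002	STERNE JAC	2011	BMJ-BRIT MED J	343		10.1136/bmj.d4002
VIECHTBAUER W, 2010, J STAT SOFTW, V36, P1	VIECHTBAUER W	2010	J STAT SOFTW	36	1
ORWIN RG, 1983, J EDUC STAT, V8, P157	ORWIN RG	1983	J EDUC STAT	8	157
ROSENTHAL R, 1979, PSYCHOL BULL, V86, P638	ROSENTHAL R	1979	PSYCHOL BULL	86	638
DUVAL S, 2000, BIOMETRICS, V56, P455	DUVAL S	2000	BIOMETRICS	56	455
GREENLAND S, 1987, EPIDEMIOL REV, V9, P1	GREENLAND S	1987	EPIDEMIOL REV	9	1
BERLIN JA, 1989, LANCET, V2, P971	BERLIN JA	1989	LANCET	2	971
CARLIN JB, 1992, STAT MED, V11, P141	CARLIN JB	1992	STAT MED	11	141
SUTTON AJ, 2000, METHODS METAANALYSIS	SUTTON AJ	2000	METHODS METAANALYSIS
SONG F, 2010, HEALTH TECHNOL ASSES, V14, DOI 10.3310/hta14080	SONG F	2010	HEALTH TECHNOL ASSES	14		10.3310/hta14080
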