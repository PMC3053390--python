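family	gene	ortholog	function	start	end	strand
I	OG-BBa0066E18.4	LOC_Os06g04690	Putative F-box protein	156499	161044	-
I	OG-BBa0049I08.11	LOC_Os06g04980	Putative F-box protein	315435	318859	+
II	OG-BBa0017A24.2	LOC_Os06g04830	Putative LRR protein	195957	198903	-
II	OG-BBa0017A24.3	LOC_Os06g04840	Putative LRR protein	204593	207258	-
III	OG-BBa0017A24.4	LOC_Os06g04850	Putative protein	216110	217001	+
III	OG-BBa0017A24.6	LOC_Os06g04870	Putative protein	229920	230963	+
IV	OG-BBa0049I08.3	LOC_Os06g04930	Putative ENOD93 protein	267102	267855	-
IV	OG-BBa0049I08.5	LOC_Os06g04940	Putative ENOD93 protein	273413	274012	-
IV	OG-BBa0049I08.6	LOC_Os06g04950	Putative ENOD93 protein	277419	277981	-
IV	OG-BBa0049I08.12	LOC_Os06g04990	Putative ENOD93 protein	320002	320651	-
IV	OG-BBa0049I08.13	LOC_Os06g05000	Putative ENOD93 protein	325881	326408	-
IV	OG-BBa0049I08.14	LOC_Os06g05010	Putative ENOD93 protein	328903	329477	-
IV	OG-BBa0049I08.15	LOC_Os06g05020	Putative ENOD93 protein	332839	333419	-
V	OG-BBa0088O22.2	LOC_Os06g05209	Putative Pectate lyase protein	456489	457642	-
V	OG-BBa0088O22.3	LOC_Os06g05260	Putative Pectate lyase protein	461242	462685	-
V	OG-BBa0088O22.7	LOC_Os06g05272	Putative Pectate lyase protein	503408	504867	+
VI	OG-BBa0088O22.8	LOC_Os06g05284	Putative Transferase	506199	507791	+
VI	OG-BBa0088O22.9	LOC_Os06g05300	Putative Transferase	509461	511398	+
VI	OG-BBa0088O22.10	LOC_Os06g05310	Putative Transferase	512912	515793	+
VI	OG-BBa0088O22.11	LOC_Os06g05320	Putative Transferase	521812	522540	+
VII	OG-BBa0056F23.12	LOC_Os06g05560	Putative protein	632773	635500	+
VII	OG-BBa0056F23.13	LOC_Os06g05580	Putative F-box protein	638676	639857	+
VII	OG-BBa0056F23.14	LOC_Os06g05590	Putative F-box protein	641606	642834	+
VII	OG-BBa0056F23.15	LOC_Os06g05600	Putative F-box protein	643777	644970	+
VII	OG-BBa0056F23.16	LOC_Os06g05610	Putative F-box protein	646377	647636	+
VII	OG-BBa0056F23.17	LOC_Os06g05620	Putative F-box protein	650971	652272	+
VIII	OG-BBa0056F23.11	LOC_Os06g05550	GDSL esterase/lipase protein	630402	632063	+
VIII	OG-BBa0056F23.18	LOC_Os06g05630	GDSL esterase/lipase protein	655875	657747	+
IX	OG-BBa0041E07.3	LOC_Os06g05690	putative Cystein synthase protein	676063	678199	+
IX	OG-BBa0041E07.4	LOC_Os06g05700	putative Cystein synthase protein	681007	683334	+
X	OG-BBa0041E07.9	LOC_Os06g05750	Putative Transferase protein	695968	697392	+
X	OG-BBa0041E07.12	LOC_Os06g05790	Putative Transferase protein	710049	711485	-
XI	OG-BBa0041E07.21	LOC_Os06g05900	Putative Methylase protein	759933	764709	+
XI	OG-BBa0041E07.22	LOC_Os06g05910	Putative Methyltransferases	766462	768723	+
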