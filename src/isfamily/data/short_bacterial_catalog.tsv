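name	group	taxon_group	is_length_bp	tnp_length_aa	tir_bp	tsd_bp	clade	accession
IS26	gram_negative	Gammaproteobacteria	820	234	14	8	I	X00011
IS1006	gram_negative	Gammaproteobacteria	819	234	16	nd	I	NC_004361
IS1007	gram_negative	Gammaproteobacteria	819	234	18	nd	I	AJ250860
IS1008	gram_negative	Gammaproteobacteria	820	234	17	nd	I	AJ251307
IS1327	gram_negative	Gammaproteobacteria	810	234	15/16	nd	IV	X87144
IS1635	gram_negative	Gammaproteobacteria	861	245	14	nd	I	Y18002
IS6100	gram_negative	Gammaproteobacteria	880	254	14	8	I	X53635
ISEas1	gram_negative	Gammaproteobacteria	811	231	16	nd	IV	CP011588
ISEc59	gram_negative	Gammaproteobacteria	891	240	17/23	nd	VI	KX246266
ISPpr9	gram_negative	Gammaproteobacteria	858	245	18/22	nd	I	NC_005871
ISPsa2	gram_negative	Gammaproteobacteria	863	242	17/19	nd	V	HM563000
ISSba18	gram_negative	Gammaproteobacteria	829	230	14/16	nd	IV	NC_009999
ISVsa4	gram_negative	Gammaproteobacteria	861	246	15/18	nd	I	NC_011311
ISYps1	gram_negative	Gammaproteobacteria	809	231	16	8	IV	FM178282
IS2020	gram_negative	Alphaproteobacteria	815	228	16/19	nd	IV	AF118548
ISApr5	gram_negative	Alphaproteobacteria	806	231	11/12	nd	III	NZ_ABHC01000011
ISBj7	gram_negative	Alphaproteobacteria	824	253	14/16	nd	III	BA000040
ISMex25	gram_negative	Alphaproteobacteria	887	250	13/15	nd	VI	CP001513
ISMno28	gram_negative	Alphaproteobacteria	892	250	18/21	nd	VI	NC_011892
ISMno34	gram_negative	Alphaproteobacteria	889	250	14/15	nd	VI	NC_011892
ISMno36	gram_negative	Alphaproteobacteria	888	250	15/18	nd	VI	NC_011892
ISMno37	gram_negative	Alphaproteobacteria	889	250	25/34	nd	VI	NC_011894
ISMno6	gram_negative	Alphaproteobacteria	816	233	15	nd	VI	NC_011887
ISMpo1	gram_negative	Alphaproteobacteria	888	250	15/16	nd	VI	NC_010727
ISMtsp1	gram_negative	Alphaproteobacteria	893	250	15	nd	VI	NZ_ABAY01000077
ISMtsp2	gram_negative	Alphaproteobacteria	894	250	16/18	nd	VI	NZ_ABAT01000047
ISPko6	gram_negative	Alphaproteobacteria	817	227	15/19	nd	IV	KP294352
ISPpa9	gram_negative	Alphaproteobacteria	812	236	15	nd	III	EU909903
ISPmar1	gram_negative	Alphaproteobacteria	821	227	18/21	8	IV	GU997095
ISRle39A	gram_negative	Alphaproteobacteria	890	250	18/22	nd	VI	X99520
ISRle6	gram_negative	Alphaproteobacteria	891	256	15/17	nd	VI	NC_008382
ISRle7	gram_negative	Alphaproteobacteria	891	250	14	nd	VI	NC_008382
ISRH1	gram_negative	Alphaproteobacteria	809	250	15/16	nd	III	AF023675
ISRsp9	gram_negative	Alphaproteobacteria	818	237	18/20	nd	III	FO082821
ISRssp3	gram_negative	Alphaproteobacteria	810	236	20/24	nd	III	NZ_AAMC01000007
ISStag1	gram_negative	Alphaproteobacteria	889	255	17/18	nd	I	NZ_AAUW01000024
ISBmu21	gram_negative	Betaproteobacteria	836	240	18/24	nd	IV	AP009387
IS1628	gram_negative	Actinobacteria	841	236	20	nd	I	AF121000
ISAcma1	gram_negative	Cyanobacteria	844	236	13/14	nd	V	NC_009932
ISCca2	gram_negative	Bacteroidetes	834	235	12/13	8	IV	CBQZ010000005
ISCef5	gram_negative	Actinobacteria	843	236	21/23	nd	I	NC_004320
ISDge13	gram_negative	Deinococcus-Thermus	806	237	19	nd	III	NC_009939
ISDge15	gram_negative	Deinococcus-Thermus	747	230	16/17	nd	III	NC_008010
ISSus3	gram_negative	Acidobacteria	823	237	33/34	nd	V	NC_003106
IS1216E	gram_positive	Firmicutes Bacilli	808	226	24	nd	II	U49512
IS240A	gram_positive	Firmicutes Bacilli	861	235	16/17	nd	V	M23740
IS240C	gram_positive	Firmicutes Bacilli	817	241	16/17	nd	V	CP015730
IS257-2	gram_positive	Firmicutes Bacilli	790	221	20/26	8	II	X53951
IS257R1	gram_positive	Firmicutes Bacilli	790	224	18/20	8	II	M13290
ISBth6	gram_positive	Firmicutes Bacilli	864	238	17/18	nd	V	NZ_AAJM01000806
ISBth20	gram_positive	Firmicutes Bacilli	808	228	16/18	nd	II	CP003766
ISBwe2	gram_positive	Firmicutes Bacilli	863	235	16	nd	V	NC_010180
ISBwe3	gram_positive	Firmicutes Bacilli	843	235	15/16	nd	V	NC_010180
ISCap	gram_positive	Firmicutes Bacilli	793	224	22	nd	II	EF177828
ISEnfa1	gram_positive	Firmicutes Bacilli	808	228	18/19	nd	II	KX579977
ISLgar4	gram_positive	Firmicutes Bacilli	809	223	17/18	nd	II	AMFE010000010
ISLmo3	gram_positive	Firmicutes Bacilli	807	226	17	nd	II	CP022021
ISLmo4	gram_positive	Firmicutes Bacilli	812	226	17	nd	II	CP006611
ISS1N	gram_positive	Firmicutes Bacilli	808	226	18	8	II	M37395
ISS1S	gram_positive	Firmicutes Bacilli	808	226	18	8	II	M18294
ISS1W	gram_positive	Firmicutes Bacilli	809	226	17/18	8	II	M37396
ISSau6	gram_positive	Firmicutes Bacilli	793	224	21/22	nd	II	NC_002952
ISSau10	gram_positive	Firmicutes Bacilli	793	225	16	8	II	FN390947
ISTeha2	gram_positive	Firmicutes Bacilli	809	226	17	nd	II	AP012046
ISFal2	gram_positive	Actinobacteria	826	236	13/19	nd	Solo	NC_008278
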