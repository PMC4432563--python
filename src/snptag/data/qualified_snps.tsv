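snp_id	chrom	pos	ref	alt	gene	maf	gc_content	mappability
tagmenu000	2	2763461	T	A	GENEA	0.4186	0.4282	1.0
tagmenu001	1	2032098	C	T	GENEB	0.4011	0.4493	1.0
tagmenu002	2	751056	C	G	GENEC	0.4751	0.4991	1.0
tagmenu003	20	2335827	C	T	GENED	0.4386	0.4287	1.0
tagmenu004	6	3466224	G	T	GENEE	0.4275	0.4034	1.0
tagmenu005	14	1263870	T	G	GENEF	0.4691	0.4873	1.0
tagmenu006	9	1149134	C	A	GENEG	0.4578	0.4738	1.0
tagmenu007	11	3181407	T	A	GENEH	0.4349	0.3931	1.0
tagmenu008	21	1311651	C	G	GENEI	0.4224	0.5199	1.0
tagmenu009	14	746413	C	G	GENEJ	0.4402	0.4736	1.0
tagmenu010	21	4588172	A	C	GENEK	0.4293	0.5230	1.0
tagmenu011	6	4962802	G	C	GENEL	0.4024	0.4511	1.0
tagmenu012	11	2646957	C	A	GENEM	0.4101	0.4442	1.0
tagmenu013	14	641439	A	T	GENEN	0.4031	0.4350	1.0
tagmenu014	15	4125734	T	C	GENEO	0.4694	0.4226	1.0
tagmenu015	16	2406834	G	T	GENEP	0.4012	0.4189	1.0
tagmenu016	4	3218084	T	G	GENEQ	0.4812	0.5320	1.0
tagmenu017	14	681522	C	G	GENER	0.4876	0.4564	1.0
tagmenu018	14	1696850	C	A	GENES	0.4435	0.4843	1.0
tagmenu019	7	3488098	A	C	GENET	0.4028	0.4384	1.0
tagmenu020	1	3066206	C	G	GENEA	0.4685	0.3852	1.0
tagmenu021	22	1931899	A	C	GENEB	0.4395	0.3762	1.0
tagmenu022	16	44074	T	C	GENEC	0.4102	0.4306	1.0
tagmenu023	3	4134312	A	C	GENED	0.4848	0.5127	1.0
tagmenu024	7	2685299	T	C	GENEE	0.4759	0.4548	1.0
tagmenu025	1	3302859	G	C	GENEF	0.4322	0.4265	1.0
tagmenu026	17	4506354	C	A	GENEG	0.4665	0.4562	1.0
tagmenu027	22	3489305	A	G	GENEH	0.4600	0.4079	1.0
tagmenu028	11	3490592	A	C	GENEI	0.4621	0.4630	1.0
tagmenu029	20	1995758	G	C	GENEJ	0.4488	0.5320	1.0
tagmenu030	8	2181729	A	G	GENEK	0.4396	0.5144	1.0
tagmenu031	7	805374	A	T	GENEL	0.4644	0.3963	1.0
tagmenu032	14	4902650	G	C	GENEM	0.4297	0.5281	1.0
tagmenu033	15	2734938	G	A	GENEN	0.4218	0.3614	1.0
tagmenu034	11	1887456	T	G	GENEO	0.4480	0.4972	1.0
tagmenu035	17	2689196	A	G	GENEP	0.4361	0.4776	1.0
tagmenu036	2	1235844	G	C	GENEQ	0.4065	0.4563	1.0
tagmenu037	6	182292	C	G	GENER	0.4510	0.4021	1.0
tagmenu038	7	2606387	G	C	GENES	0.4295	0.3772	1.0
tagmenu039	16	2891965	G	T	GENET	0.4211	0.4335	1.0
tagmenu040	9	1663996	G	A	GENEA	0.4160	0.4391	1.0
tagmenu041	1	633389	C	T	GENEB	0.4368	0.3958	1.0
tagmenu042	8	1751935	G	C	GENEC	0.4538	0.3693	1.0
tagmenu043	2	575714	C	G	GENED	0.4733	0.5094	1.0
tagmenu044	13	1654641	C	G	GENEE	0.4290	0.4087	1.0
tagmenu045	7	291609	T	C	GENEF	0.4241	0.5316	1.0
tagmenu046	22	3005517	G	C	GENEG	0.4800	0.5287	1.0
tagmenu047	1	3964327	A	T	GENEH	0.4315	0.4622	1.0
tagmenu048	4	1389265	C	A	GENEI	0.4598	0.4946	1.0
tagmenu049	7	2553330	T	A	GENEJ	0.4916	0.5158	1.0
tagmenu050	13	4685211	C	A	GENEK	0.4158	0.4022	1.0
tagmenu051	18	4113895	C	A	GENEL	0.4429	0.4813	1.0
tagmenu052	18	100560	G	C	GENEM	0.4783	0.5326	1.0
tagmenu053	20	4960405	A	T	GENEN	0.4172	0.5301	1.0
tagmenu054	15	3005717	G	T	GENEO	0.4721	0.4537	1.0
tagmenu055	12	1011338	G	A	GENEP	0.4399	0.4556	1.0
tagmenu056	21	2342419	G	C	GENEQ	0.4278	0.3797	1.0
tagmenu057	12	3157483	T	C	GENER	0.4822	0.4984	1.0
tagmenu058	7	2097446	A	G	GENES	0.4132	0.3785	1.0
tagmenu059	4	2434033	T	C	GENET	0.4744	0.5042	1.0
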