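snp_id	AFR	EUR	ASN	AMR
tag000	0.4375	0.4260	0.4274	0.4404
tag001	0.4365	0.4448	0.4449	0.4348
tag002	0.4829	0.5000	0.4556	0.4894
tag003	0.4475	0.4752	0.4782	0.4651
tag004	0.4672	0.4380	0.4404	0.4407
tag005	0.4342	0.4464	0.4158	0.4168
tag006	0.4557	0.4640	0.4863	0.4870
tag007	0.4281	0.4399	0.4343	0.4134
tag008	0.4787	0.4307	0.4580	0.4675
tag009	0.4380	0.4238	0.4431	0.4147
tag010	0.4660	0.4574	0.4831	0.4835
tag011	0.4892	0.4860	0.4765	0.4802
tag012	0.4342	0.4585	0.4518	0.4838
tag013	0.4876	0.4753	0.4736	0.4606
tag014	0.4535	0.4466	0.4321	0.4440
tag015	0.4666	0.4569	0.4900	0.4650
tag016	0.4706	0.4688	0.4558	0.4553
tag017	0.4494	0.4490	0.4394	0.4697
tag018	0.4706	0.4919	0.4528	0.4695
tag019	0.4446	0.4609	0.4546	0.4895
tag020	0.4398	0.4033	0.4161	0.4110
tag021	0.4779	0.4441	0.4940	0.4871
tag022	0.4099	0.4049	0.4245	0.4353
tag023	0.4501	0.4732	0.4637	0.4412
tag024	0.4721	0.4628	0.4643	0.4874
tag025	0.4444	0.4619	0.4702	0.4523
tag026	0.4094	0.4340	0.4218	0.4000
tag027	0.4558	0.4335	0.4656	0.4827
tag028	0.4672	0.4597	0.4442	0.4314
tag029	0.4271	0.4451	0.4441	0.4537
low000	0.0286	0.0331	0.0288	0.0259
low001	0.0738	0.0963	0.0923	0.0982
low002	0.0901	0.0808	0.0961	0.0947
low003	0.0643	0.0730	0.0391	0.0563
low004	0.0160	0.0114	0.0123	0.0244
low005	0.0690	0.0649	0.0446	0.0331
low006	0.0519	0.0330	0.0502	0.0384
low007	0.0721	0.0779	0.0840	0.0728
low008	0.0571	0.0246	0.0188	0.0258
low009	0.0743	0.0441	0.0579	0.0752
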