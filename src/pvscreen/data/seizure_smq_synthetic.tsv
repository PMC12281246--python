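set_name	pt_code	pt_label	status
seizure_smq_narrow	90010001	Synthetic seizure term 01	include
seizure_smq_narrow	90010002	Synthetic seizure term 02	include
seizure_smq_narrow	90010003	Synthetic seizure term 03	include
seizure_smq_narrow	90010004	Synthetic seizure term 04	include
seizure_smq_narrow	90010005	Synthetic seizure term 05	include
seizure_smq_narrow	90010006	Synthetic seizure term 06	include
seizure_smq_narrow	90010007	Synthetic seizure term 07	include
seizure_smq_narrow	90010008	Synthetic seizure term 08	include
seizure_smq_narrow	90010009	Synthetic seizure term 09	include
seizure_smq_narrow	90010010	Synthetic seizure term 10	include
seizure_smq_narrow	90010011	Synthetic seizure term 11	include
seizure_smq_narrow	90010012	Synthetic seizure term 12	include
seizure_smq_narrow	90010013	Synthetic seizure term 13	include
seizure_smq_narrow	90010014	Synthetic seizure term 14	include
seizure_smq_narrow	90010015	Synthetic seizure term 15	include
seizure_smq_narrow	90010016	Synthetic seizure term 16	include
seizure_smq_narrow	90010017	Synthetic seizure term 17	include
seizure_smq_narrow	90010018	Synthetic seizure term 18	include
seizure_smq_narrow	90010019	Synthetic seizure term 19	include
seizure_smq_narrow	90010020	Synthetic seizure term 20	include
seizure_smq_narrow	90010021	Synthetic seizure term 21	include
seizure_smq_narrow	90010022	Synthetic seizure term 22	include
seizure_smq_narrow	90010023	Synthetic seizure term 23	include
seizure_smq_narrow	90010024	Synthetic seizure term 24	include
seizure_smq_narrow	90010025	Synthetic seizure term 25	include
seizure_smq_narrow	90010026	Synthetic seizure term 26	include
seizure_smq_narrow	90010027	Synthetic seizure term 27	include
seizure_smq_narrow	90010028	Synthetic seizure term 28	include
seizure_smq_narrow	90010029	Synthetic seizure term 29	include
seizure_smq_narrow	90010030	Synthetic seizure term 30	include
seizure_smq_narrow	90010031	Synthetic seizure term 31	include
seizure_smq_narrow	90010032	Synthetic seizure term 32	include
seizure_smq_narrow	90010033	Synthetic seizure term 33	include
seizure_smq_narrow	90010034	Synthetic seizure term 34	include
seizure_smq_narrow	90010035	Synthetic seizure term 35	include
seizure_smq_narrow	90010036	Synthetic seizure term 36	include
seizure_smq_narrow	90010037	Synthetic seizure term 37	include
seizure_smq_narrow	90010038	Synthetic seizure term 38	include
seizure_smq_narrow	90010039	Synthetic seizure term 39	include
seizure_smq_narrow	90010040	Synthetic seizure term 40	include
seizure_smq_narrow	90010041	Synthetic seizure term 41	include
seizure_smq_narrow	10076981	Post-stroke seizure	exclude
seizure_smq_narrow	10036312	Post-traumatic epilepsy	exclude
seizure_smq_narrow	90020001	Synthetic non-drug-induced seizure term 01	exclude
seizure_smq_narrow	90020002	Synthetic non-drug-induced seizure term 02	exclude
seizure_smq_narrow	90020003	Synthetic non-drug-induced seizure term 03	exclude
seizure_smq_narrow	90020004	Synthetic non-drug-induced seizure term 04	exclude
seizure_smq_narrow	90020005	Synthetic non-drug-induced seizure term 05	exclude
seizure_smq_narrow	90020006	Synthetic non-drug-induced seizure term 06	exclude
seizure_smq_narrow	90020007	Synthetic non-drug-induced seizure term 07	exclude
seizure_smq_narrow	90020008	Synthetic non-drug-induced seizure term 08	exclude
seizure_smq_narrow	90020009	Synthetic non-drug-induced seizure term 09	exclude
seizure_smq_narrow	90020010	Synthetic non-drug-induced seizure term 10	exclude
seizure_smq_narrow	90020011	Synthetic non-drug-induced seizure term 11	exclude
seizure_smq_narrow	90020012	Synthetic non-drug-induced seizure term 12	exclude
seizure_smq_narrow	90020013	Synthetic non-drug-induced seizure term 13	exclude
seizure_smq_narrow	90020014	Synthetic non-drug-induced seizure term 14	exclude
seizure_smq_narrow	90020015	Synthetic non-drug-induced seizure term 15	exclude
seizure_smq_narrow	90020016	Synthetic non-drug-induced seizure term 16	exclude
seizure_smq_narrow	90020017	Synthetic non-drug-induced seizure term 17	exclude
seizure_smq_narrow	90020018	Synthetic non-drug-induced seizure term 18	exclude
seizure_smq_narrow	90020019	Synthetic non-drug-induced seizure term 19	exclude
seizure_smq_narrow	90020020	Synthetic non-drug-induced seizure term 20	exclude
seizure_smq_narrow	90020021	Synthetic non-drug-induced seizure term 21	exclude
seizure_smq_narrow	90020022	Synthetic non-drug-induced seizure term 22	exclude
seizure_smq_narrow	90020023	Synthetic non-drug-induced seizure term 23	exclude
seizure_smq_narrow	90020024	Synthetic non-drug-induced seizure term 24	exclude
seizure_smq_narrow	90020025	Synthetic non-drug-induced seizure term 25	exclude
seizure_smq_narrow	90020026	Synthetic non-drug-induced seizure term 26	exclude
seizure_smq_narrow	90020027	Synthetic non-drug-induced seizure term 27	exclude
seizure_smq_narrow	90020028	Synthetic non-drug-induced seizure term 28	exclude
seizure_smq_narrow	90020029	Synthetic non-drug-induced seizure term 29	exclude
seizure_smq_narrow	90020030	Synthetic non-drug-induced seizure term 30	exclude
seizure_smq_narrow	90020031	Synthetic non-drug-induced seizure term 31	exclude
seizure_smq_narrow	90020032	Synthetic non-drug-induced seizure term 32	exclude
seizure_smq_narrow	90020033	Synthetic non-drug-induced seizure term 33	exclude
seizure_smq_narrow	90020034	Synthetic non-drug-induced seizure term 34	exclude
seizure_smq_narrow	90020035	Synthetic non-drug-induced seizure term 35	exclude
seizure_smq_narrow	90020036	Synthetic non-drug-induced seizure term 36	exclude
seizure_smq_narrow	90020037	Synthetic non-drug-induced seizure term 37	exclude
seizure_smq_narrow	90020038	Synthetic non-drug-induced seizure term 38	exclude
seizure_smq_narrow	90020039	Synthetic non-drug-induced seizure term 39	exclude
seizure_smq_narrow	90020040	Synthetic non-drug-induced seizure term 40	exclude
seizure_smq_narrow	90020041	Synthetic non-drug-induced seizure term 41	exclude
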