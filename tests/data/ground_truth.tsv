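patient_id	label	index_atc	start_dose_level	start_status	has_maintenance	maintenance_dose	titration
P00000	included	N06AA10	0.15	valid	False		
P00001	included	N06AB03	1.0	valid	True	2.0	up
P00002	included	N06AX11	1.0	valid	True	1.0	same
P00003	included	N06AA09	0.1	valid	False		
P00004	included	N06AB03	0.5	valid	True	1.0	up
P00005	included	N06AX16	1.5	valid	True	1.5	same
P00006	included	N06AB04	1.0	valid	True	1.0	same
P00007	included	N06AB04	1.0	too_low	True	1.0	
P00008	included	N06AB04	1.0	valid	False		
P00009	no_antidepressant						
P00010	included	N06AA02	0.1	valid	False		
P00011	included	N06AA09	0.2	valid	True	0.2	same
P00012	included	N06AB05	0.5	valid	False		
P00013	included	N06AB05	1.0	valid	True	2.0	up
P00014	included	N06AB05	0.5	valid	True	1.0	up
P00015	included	N06AB04	0.4	valid	False		
P00016	included	N06AB06	0.5	valid	True	0.5	same
P00017	included	N06AB04	1.0	valid	True	1.0	same
P00018	included	N06AA09	0.4	valid	True	0.4	same
P00019	included	N06AX05	0.33	valid	False		
P00020	included	N06AB06	0.5	valid	False		
P00021	included	N06AA09	0.4	valid	False		
P00022	included	N06AB05	0.5	valid	True	1.0	up
P00023	included	N06AB03	0.5	valid	False		
P00024	included	N06AA04	0.5	too_low	False		
P00025	included	N06AB05	1.0	valid	True	2.0	up
P00026	included	N06AB05	1.0	valid	True	1.0	same
P00027	included	N06AB04	1.0	valid	True	2.0	up
P00028	included	N06AA09	0.8	valid	True	0.8	same
P00029	included	N06AB03	0.5	valid	False		
P00030	included	N06AB05	1.0	too_low	False		
P00031	included	N06AB04	1.0	valid	True	0.5	down
P00032	included	N06AB06	1.0	valid	True	1.5	up
P00033	included	N06AX11	0.5	valid	True	0.5	same
P00034	included	N06AX11	0.5	valid	True	0.5	same
P00035	included	N06AA09	0.2	valid	True	0.2	same
P00036	included	N06AB04	1.0	valid	True	1.0	same
P00037	included	N06AA09	0.1	valid	False		
P00038	included	N06AB04	0.4	valid	True	0.4	same
P00039	included	N06AB03	1.0	valid	False		
P00040	included	N06AA09	0.1	valid	False		
P00041	included	N06AX11	0.5	valid	True	0.5	same
P00042	included	N06AX16	1.5	valid	False		
P00043	included	N06AX05	0.17	valid	True	0.17	same
P00044	included	N06AB05	1.0	valid	True	1.0	same
P00045	no_antidepressant						
P00046	included	N06AB05	1.0	valid	True	1.0	same
P00047	included	N06AB03	1.0	valid	False		
P00048	included	N06AB06	1.0	valid	False		
P00049	included	N06AA04	0.5	valid	True	0.5	same
P00050	age	N06AA09					
P00051	included	N06AB06	1.0	valid	False		
P00052	included	N06AB06	1.0	valid	True	1.0	same
P00053	no_antidepressant						
P00054	included	N06AX16	0.75	valid	False		
P00055	included	N06AA09	0.4	valid	False		
P00056	included	N06AB03	1.0	valid	False		
P00057	included	N06AB04	0.4	too_low	False		
P00058	included	N06AX11	0.5	valid	True	0.5	same
P00059	included	N06AB08	0.5	too_low	False		
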