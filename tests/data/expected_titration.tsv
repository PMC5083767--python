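patient_id	direction
P00001	up
P00002	same
P00004	up
P00005	same
P00006	same
P00011	same
P00013	up
P00014	up
P00016	same
P00017	same
P00018	same
P00022	up
P00025	up
P00026	same
P00027	up
P00028	same
P00031	down
P00032	up
P00033	same
P00034	same
P00035	same
P00036	same
P00038	same
P00041	same
P00043	same
P00044	same
P00046	same
P00049	same
P00052	same
P00058	same
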