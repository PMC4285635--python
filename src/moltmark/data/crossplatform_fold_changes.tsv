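# Day 3 vs day 10 log2 fold changes for the 12 profiled molt-cycle genes,
# measured by RNA-seq (illumina_log2fc) and qPCR (qpcr_log2fc); positive =
# higher expression on day 10. range_fc is the untransformed fold change
# between the minimum and maximum qPCR expression observed across the stage.
gene	illumina_log2fc	qpcr_log2fc	range_fc
FABP	-2.24	-3.45	15.6
ELOV	-4.72	-4.74	30.0
HR78	-2.06	-1.26	12.8
ERR	-2.17	-1.84	5.3
HR3	3.21	3.84	64.2
HR38a	2.65	2.25	5.9
Vtg	3.20	1.15	597.9
Torso-like	9.26	8.24	1024.2
FTZ-F1	3.25	4.25	32.0
HR38b	2.26	1.07	7.8
EcR	1.10	1.06	3.4
Fem-1	4.43	1.33	7.6
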