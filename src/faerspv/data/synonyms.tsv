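verbatim	generic	provenance
OPDIVO	nivolumab	demo
NIVOLUMAB	nivolumab	demo
KEYTRUDA	pembrolizumab	demo
PEMBROLIZUMAB	pembrolizumab	demo
DUPIXENT	dupilumab	demo
DUPILUMAB	dupilumab	demo
YERVOY	ipilimumab	demo
IPILIMUMAB	ipilimumab	demo
COSENTYX	secukinumab	demo
SECUKINUMAB	secukinumab	demo
POTELIGEO	mogamulizumab	demo
MOGAMULIZUMAB	mogamulizumab	demo
ALDARA	imiquimod	demo
IMIQUIMOD	imiquimod	demo
ARALEN	chloroquine	demo
CHLOROQUINE	chloroquine	demo
CHLOROQUINE PHOSPHATE	chloroquine	demo
STELARA	ustekinumab	demo
USTEKINUMAB	ustekinumab	demo
TALTZ	ixekizumab	demo
IXEKIZUMAB	ixekizumab	demo
TREMFYA	guselkumab	demo
GUSELKUMAB	guselkumab	demo
SKYRIZI	risankizumab	demo
RISANKIZUMAB	risankizumab	demo
PROSCAR	finasteride	demo
PROPECIA	finasteride	demo
FINASTERIDE	finasteride	demo
PRILOSEC	omeprazole	demo
OMEPRAZOLE	omeprazole	demo
NEXIUM	esomeprazole	demo
ESOMEPRAZOLE	esomeprazole	demo
ACIPHEX	rabeprazole	demo
RABEPRAZOLE	rabeprazole	demo
TECENTRIQ	atezolizumab	demo
ATEZOLIZUMAB	atezolizumab	demo
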