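gene	allele	function
NUDT15	*1	normal
NUDT15	*2	no_function
NUDT15	*3	no_function
NUDT15	*9	no_function
TPMT	*1	normal
TPMT	*2	no_function
TPMT	*3A	no_function
TPMT	*3B	no_function
TPMT	*3C	no_function
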