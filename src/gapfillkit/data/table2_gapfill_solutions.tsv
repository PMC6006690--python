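biocyc_id	added_by
ASNSYNA-RXN	A
RXN-1381	A
DUDPKIN-RXN	A,*
CDPKIN-RXN	A,*
DTDPKIN-RXN	A,M
UDPKIN-RXN	A,M
GPPSYN-RXN	A,M
FPPSYN-RXN	A,M
RXN-8999	A,M
IGPSYN-RXN	A,M
HISTIDPHOS-RXN	A,M
PREPHENATE-TRANSAMINE-RXN	A,M
RXN-12460	M
GDPKIN-RXN	M
GLUCOKIN-RXN	M
RXN-17018	M
RXN-17897	M
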