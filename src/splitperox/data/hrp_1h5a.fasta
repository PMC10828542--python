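>HRP_C1A horseradish peroxidase C1A, mature chain, numbering as PDB 1H5A chain A (1-308)
QLTPTFYDNSCPNVSNIVRDTIVNELRSDPRIAASILRLHFHDCFVNGCDASILLDNTTS
FRTEKDAFGNANSARGFPVIDRMKAAVESACPRTVSCADLLTIAAQQSVTLAGGPSWRVP
LGRRDSLQAFLDLANANLPAPFFTLPQLKDSFRNVGLNRSSDLVALSGGHTFGKNQCRFI
MDRLYNFSNTGLPDPTLNTTYLQTLRGLCPLNGNLSALVDFDLRTPTIFDNKYYVNLEEQ
KGLIQSDQELFSSPNATDTIPLVRSFANSTQTFFNAFVEAMDRMGNITPLTGTQGQIRLN
CRVVNSNS
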