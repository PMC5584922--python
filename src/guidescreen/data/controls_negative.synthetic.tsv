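# SYNTHETIC placeholder negative-control spacers (20 nt). In a real design
# these would target validated safe-harbor loci; replace with your own list.
neg_safeharbor_01	ACGTTAGCATCCAGATTACA
neg_safeharbor_02	TTACGGATCATGCAAGCTTA
neg_safeharbor_03	CATTAGCAACGTTCAGATCA
neg_safeharbor_04	GATCCATTACAGTACGATCA
neg_safeharbor_05	ATCGATTACCAGTTCAGCAT
neg_safeharbor_06	TCAGATCACGATTACATGCA
neg_safeharbor_07	CGATTACAGCATTCAGATCA
neg_safeharbor_08	ATTCAGCATCGATTACAGTA
neg_safeharbor_09	GCATTACAGATCCATTAGCA
neg_safeharbor_10	TACAGATTCAGCATCGATCA
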