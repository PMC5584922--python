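# SYNTHETIC placeholder positive-control spacers (20 nt). In a real design
# these would target essential genes (e.g. ribosomal proteins); replace with
# your own validated list.
pos_essential_01	GCCATTACAGATCAGTTACG
pos_essential_02	CAGTTACGGCATTACAGATC
pos_essential_03	ATCAGTTACGCATTACGGCA
pos_essential_04	TACGGCATTACAGATCAGTT
pos_essential_05	GATCAGTTACGGCATTACAG
pos_essential_06	ACAGATCAGTTACGGCATTA
pos_essential_07	TTACGGCATTACAGATCAGT
pos_essential_08	CATTACAGATCAGTTACGGC
pos_essential_09	AGTTACGGCATTACAGATCA
pos_essential_10	GGCATTACAGATCAGTTACG
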