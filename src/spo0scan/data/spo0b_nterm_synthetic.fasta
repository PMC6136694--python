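>Spo0B_nterm_synthetic first 50 aa, synthetic stand-in
NWPQAVSWMIKTFAKNWIFHELRTPLKKITWYRMHYGGVATDQEGTMASY
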