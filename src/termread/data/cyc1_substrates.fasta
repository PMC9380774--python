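>pcCYC1 precleaved CYC1 RNA substrate, 5'FAM; ends at the cleavage site
UUUAUAGUUAUGUUAGUAUUAAGAACGUUAUUUAUAUUUCAA
>CYC1 uncleaved CYC1 RNA substrate with 3' extension, 5'FAM / 3'Alexa647
UUUAUAGUUAUGUUAGUAUUAAGAACGUUAUUUAUAUUUCAAAUUUUUCUUUUUUU
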