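metabolic process
metabolism
catabolic process
response to
positive regulation of
negative regulation of
regulation of
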