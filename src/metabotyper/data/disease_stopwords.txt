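uria
emia
deficiency
disease
transient
neonatal
hyper
hypo
defect
syndrome
familial
autosomal
dominant
recessive
benign
infantile
hereditary
congenital
early-onset
idiopathic
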