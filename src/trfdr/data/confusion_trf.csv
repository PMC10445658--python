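actual,adipose,fibroglandular,tumor
adipose,691,15,55
fibroglandular,23,11,43
tumor,72,24,251
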