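actual,adipose,fibroglandular,tumor
adipose,736,3,22
fibroglandular,11,49,17
tumor,44,6,297
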