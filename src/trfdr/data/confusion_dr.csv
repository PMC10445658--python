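actual,adipose,fibroglandular,tumor
adipose,729,2,30
fibroglandular,8,49,20
tumor,60,8,279
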