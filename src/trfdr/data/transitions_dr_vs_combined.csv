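model_a,adipose,fibroglandular,tumor
adipose,28,0,32
fibroglandular,1,4,3
tumor,15,2,262
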