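model_a,adipose,fibroglandular,tumor
adipose,22,0,50
fibroglandular,0,1,23
tumor,22,5,224
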