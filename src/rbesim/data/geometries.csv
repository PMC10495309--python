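id,hlx_um,hly_um,hlz_um
1,10,10,10
2,12.5,8,10
3,20,10,5
4,5,40,5
5,5,14.1425,14.1425
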