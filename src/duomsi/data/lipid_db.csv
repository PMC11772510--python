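name,adduct,theoretical_mz
PE 34:1,[M+H]+,718.5381
PE 36:1,[M+H]+,746.5694
PC 34:1-CH3,[M+H]+,746.5694
PE 36:2,[M+H]+,744.5538
PE 38:4,[M+H]+,768.5538
PE 38:6,[M+H]+,764.5225
PE 40:6,[M+H]+,792.5538
PE O-36:5,[M+H]+,724.5276
PE O-38:5,[M+H]+,752.5589
HexCer 42:2;2,[M+H]+,810.6817
HexCer 40:1;2,[M+H]+,784.6661
PC 32:0,[M+H]+,734.5694
PC 34:1,[M+H]+,760.5851
PC 36:4,[M+H]+,782.5694
PS 40:6,[M+H]+,834.5280
SM d36:1,[M+H]+,731.6062
Cer d36:1,[M+H]+,566.5507
Cer d42:2,[M+H]+,648.6289
PC 34:1,[M+Na]+,782.5670
PE 40:6,[M+Na]+,814.5357
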