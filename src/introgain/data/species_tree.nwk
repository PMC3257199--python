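(((((((((human:0.9,mouse:0.9)Euarchontoglires:0.45,(dog:0.8,cow:0.8)Laurasiatheria:0.55)Boreoeutheria:0.25,(sloth:1.0,armadillo:1.0)Xenarthra:0.6,(elephant:0.95,tenrec:0.95)Afrotheria:0.65)Eutheria:0.4,(opossum:1.4,wallaby:1.4)Marsupialia:0.6)Theria:0.2,(platypus:1.7,echidna:1.7)Monotremata:0.5)Mammalia:0.9,(chicken:2.1,lizard:2.1)Sauropsida:1.0)Amniota:0.4,frog:3.5)Tetrapoda:0.6,zebrafish:4.1)Gnathostomata:0.8,amphioxus:4.9)Chordata;
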