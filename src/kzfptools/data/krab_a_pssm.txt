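# columns: A C D E F G H I K L M N P Q R S T V W Y
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789
0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789
0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.015789 0.700000 0.015789 0.015789 0.015789 0.015789
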