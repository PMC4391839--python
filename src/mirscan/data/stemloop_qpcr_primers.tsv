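mirna_id	stemloop_rt	forward
miR156d	ctcaactggtgtcgtggagtccggcaattcagttgaggtgctctc	acactccagctgggttgacagaag
miR156g	ctcaactggtgtcgtggagtccggcaattcagttgaggtgctctc	acactccagctgggtgacagaaga
miR166b	ctcaactggtgtcgtggagtccggcaattcagttgagccccgagc	acactccagctgggggaatgttgt
miR399a	ctcaactggtgtcgtggagtccggcaattcagttgagcagggcaa	acactccagctgggtgccaaagga
miR319m	ctcaactggtgtcgtggagtccggcaattcagttgagagggagct	acactccagctgggttggactgaa
miR160a	ctcaactggtgtcgtggagtccggcaattcagttgagtggcatac	acactccagctgggtgcctggctc
miR164e	ctcaactggtgtcgtggagtccggcaattcagttgagtgcacgtg	acactccagctgggtggagaagca
miR167c	ctcaactggtgtcgtggagtccggcaattcagttgagcagatcat	acactccagctgggtgaagctgcc
miR169h	ctcaactggtgtcgtggagtccggcaattcagttgagcaggcaag	acactccagctgggtagccaagga
miR162	ctcaactggtgtcgtggagtccggcaattcagttgagtggacgca	acactccagctgggtcgataaacc
miR5538	ctcaactggtgtcgtggagtccggcaattcagttgaggcagcaag	acactccagctgggactgaactca
miR4995	ctcaactggtgtcgtggagtccggcaattcagttgagcccttaac	acactccagctgggaggcagtggc
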