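CRYST1    1.000    1.000    1.000  90.00  90.00  90.00 P 1                      
ATOM      1  O   PKT P   1      -2.118   1.493  -0.110  1.00 20.00           O  
ATOM      2  S   PKT P   2      -2.777  -2.917  -1.357  1.00 20.00           S  
ATOM      3  O   PKT P   3       1.998   2.116  -0.273  1.00 20.00           O  
ATOM      4  S   PKT P   4       0.169   3.671  -2.499  1.00 20.00           S  
ATOM      5  O   PKT P   5      -2.200  -0.977   1.035  1.00 20.00           O  
ATOM      6  S   PKT P   6       3.081  -4.024  -1.541  1.00 20.00           S  
ATOM      7  O   PKT P   7      -1.671   1.698  -0.608  1.00 20.00           O  
ATOM      8  S   PKT P   8      -1.391   1.158  -1.105  1.00 20.00           S  
ATOM      9  O   PKT P   9       2.327  -0.992  -1.583  1.00 20.00           O  
ATOM     10  S   PKT P  10       3.861   2.154  -2.458  1.00 20.00           S  
ATOM     11  O   PKT P  11      -1.715  -1.824   1.229  1.00 20.00           O  
ATOM     12  S   PKT P  12       1.906  -3.735  -3.501  1.00 20.00           S  
ATOM     13  O   PKT P  13      -1.319   2.085  -0.023  1.00 20.00           O  
ATOM     14  S   PKT P  14      -3.973  -0.290  -1.569  1.00 20.00           S  
ATOM     15  O   PKT P  15       1.866  -0.962  -2.221  1.00 20.00           O  
ATOM     16  S   PKT P  16       4.884   2.038  -0.015  1.00 20.00           S  
ATOM     17  O   PKT P  17       0.708  -1.917  -1.308  1.00 20.00           O  
ATOM     18  S   PKT P  18      -1.114  -1.853  -3.731  1.00 20.00           S  
END                                                                             
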