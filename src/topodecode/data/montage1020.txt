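# Idealized spherical 10-20/10-10 electrode positions.
# Columns: label  inclination_deg  azimuth_deg
#   inclination: polar angle from the vertex (Cz = 0); the outermost
#     10-20 circle (Fp1, T7, Oz, ...) sits on the ear-level equator (90).
#   azimuth: measured from the nose direction, positive toward the right
#     ear, in (-180, 180].
# Cartesian convention: x = sin(incl)*sin(az)  (toward right ear)
#                       y = sin(incl)*cos(az)  (toward nose)
#                       z = cos(incl)          (toward vertex)
Fpz  90    0
Fp1  90  -18
Fp2  90   18
AF7  90  -36
AF8  90   36
F7   90  -54
F8   90   54
FT7  90  -72
FT8  90   72
T7   90  -90
T8   90   90
TP7  90 -108
TP8  90  108
P7   90 -126
P8   90  126
PO7  90 -144
PO8  90  144
O1   90 -162
O2   90  162
Oz   90  180
Cz    0    0
FCz  23    0
Fz   46    0
AFz  69    0
CPz  23  180
Pz   46  180
POz  69  180
C1   23  -90
C2   23   90
C3   46  -90
C4   46   90
C5   69  -90
C6   69   90
AF3  74  -25
AF4  74   25
F1   49  -22
F2   49   22
F3   60  -39
F4   60   39
F5   75  -49
F6   75   49
FC1  32  -45
FC2  32   45
FC3  50  -62
FC4  50   62
FC5  72  -69
FC6  72   69
CP1  32 -135
CP2  32  135
CP3  50 -118
CP4  50  118
CP5  72 -111
CP6  72  111
P1   49 -158
P2   49  158
P3   60 -141
P4   60  141
P5   75 -131
P6   75  131
PO3  74 -155
PO4  74  155
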