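# Diagnostic character strings of the three published subfamily diagnoses,
# one per line, exactly as printed (nuclear-genome list then COI-barcode list).
# Katreinae, nuclear
aly528.10.2:G940C
aly925.27.5:A3610T
aly84.77.5:T1651G
aly595.14.2:G184C
aly2284.22.2:G967C
# Katreinae, COI barcode
C235T
A335T
C347T
T349A
# Chamundinae, nuclear
aly528.10.2:A631C
aly3277.11.2:A1726G
aly4523.3.2:T143C
aly499.37.1:G77G (not A)
aly363.14.5:A76A (not C)
aly2700.1.4:T70T (not G)
# Chamundinae, COI barcode
G38A
A81C
A307G
C347T
T349A
A430T
A604C
# Barcinae, nuclear
aly525.83.3:A682T
aly525.83.3:G683C
aly1139.27.4:G112T
aly1139.27.4:G113C
aly23605.15.15:G49A
# Barcinae, COI barcode
G101A
A166G
474C
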