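# Default human olfactory-receptor exclusion list (gene symbols, editable).
# Representative OR family members; extend with a full OR symbol list for
# production use (membership is exact string match).
OR1A1
OR1A2
OR1D2
OR1E1
OR1E2
OR1G1
OR2A4
OR2B6
OR2C1
OR2F1
OR2H1
OR2H2
OR2J2
OR2J3
OR2W1
OR3A1
OR3A2
OR3A3
OR4D1
OR4F5
OR5I1
OR5P2
OR5P3
OR6A2
OR7A5
OR7A17
OR7C1
OR7C2
OR7D2
OR7E24
OR8B8
OR10A4
OR10A5
OR10H1
OR10H2
OR10H3
OR10J1
OR11A1
OR12D2
OR12D3
OR13C3
OR51B4
OR51E1
OR51E2
OR52A1
OR56A1
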