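>VTG615-synthetic deterministic 615-residue vitellogenin-like stand-in fixture (vertebrate composition, seed 20181108)
QGKWECVAFQFGLKRIGVTRPIFKFTSTTHKVVFFAACSCSNQRPMLKVHSTEATKGDGI
VINHNWDRSCSAVALREEKAYGVAKFIDVSCHCEFHDGIVVASVGSLFEEKNESEVNPYR
APTGNWAAGRVSEGIHAVGNKFCYKVRYVIACFEKGTANTHPKDIQFANMDPEHGEDIAV
KCRTNVLVLSKATKNYTAIGARICELCSQLDTQGCDEKQNLYHNQGNGGDPNMEAEAVLC
DLSPAAKCGECVEFLTRSAEKTFAYETSVKMVLGTTLMARDTCEPVQASLACFDSWSQTV
FVAALTSQCRDDFLLMTVWVRLAGTNCLAVLMQTAKMEKSSFAIKVNGVFCAPRTLGPVK
VSENASDHKNDGQYKSKIGSKDCDASDYGQARVRVKGLQLSKVKCAGYVCESYECVTCCV
LQKTHEPAKGLFALIGKREKVVMKQEHGLKNKSVCWEGCTKGGLTSGVGEGEFFPLVGEK
SVKAGVSESHLPRSQNCRGTENNRGTFRDFACALSTFNDGCYAEALFKGVQTIQFALDHK
TSVVQLASKSGMNCEKQNAYTGRGQKNKIENIDVFAGNVKNAIMCRAPRKWTIVTFGGMS
PHKQTSGKVYCRSGW
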