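# Synthetic ring-system frequency table (canonical ring-system key -> count).
# A small stand-in for a corpus-derived census (e.g. a bioactivity database);
# users can supply a full table as TSV ring_key<TAB>count.
c1ccccc1	1500000
c1ccncc1	400000
c1ccc2ccccc2c1	90000
C1CCCCC1	250000
C1CCCC1	80000
C1CCNCC1	350000
C1CCOCC1	120000
C1CNCCN1	60000
c1ccnc1	70000
c1ccoc1	50000
c1ccsc1	60000
c1cncn1	55000
c1ccc2nccc2c1	65000
c1cncnc1	90000
C1CCNC1	90000
C1COCCN1	110000
C1CCOC1	60000
c1cnccn1	40000
C1CC1	150000
C1CCC1	20000
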