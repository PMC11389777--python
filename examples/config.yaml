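# Default two-decade synthetic scenario on a 32 km planar domain.
scenario:
  seed: 1
  years: [2000, 2001, 2002, 2003, 2004, 2005, 2006, 2007, 2008, 2009,
          2010, 2011, 2012, 2013, 2014, 2015, 2016, 2017, 2018, 2019]
  segregation: 0.6
  n_tracts: 144
  total_population: 400000
grid:
  finest: 1000
  coarsest: 8000
analysis:
  partitions: [fleet, primary_secondary, exhaust_nonexhaust]
  percentiles: [75, 90]
  designations:
    ab617_analog: 0.081
    sb535_analog: 0.30
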