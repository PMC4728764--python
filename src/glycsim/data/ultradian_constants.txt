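# Metabolic constants of the two-delay glucose-insulin feedback model.
# One constant per line: name  value  unit  # note
# Values follow the standard ultradian-oscillator tabulation of the
# Sturis/Tolic/Li-Kuang-Mason model lineage (glucose state in mg, insulin
# state in mU; see docs/methods.md for the unit convention).  The f6/f7
# hyperglycemia-inhibitor constants have no Sturis analog; their values are
# documented design choices (f6 ~ 1 in the normoglycemic band, f7 engaging
# above ~300 mg/dL).
Rc     210.0    mU/min   # max pancreatic insulin release rate (f1)
c1     2000.0   mg/L     # f1 sigmoid center, glucose concentration
e1     300.0    mg/L     # f1 sigmoid steepness scale
Vg     10.0     L        # glucose distribution volume
Ub     72.0     mg/min   # max insulin-independent glucose utilization (f2)
c2     144.0    mg/L     # f2 exponential scale
c3     1000.0   mg/L     # f3 linear scale (f3 = 1 at 100 mg/dL)
Uo     40.0     mg/min   # f4 lower utilization bound
Uc     940.0    mg/min   # f4 upper utilization bound
kappa  1.77     1        # f4 log-sigmoid steepness
c4     80.0     mU/L     # f4 insulin scale
Vc     11.0     L        # f4 insulin distribution volume
Etc    20.0     L        # f4 exchange-rate x time-constant product (E*ti)
Rg     180.0    mg/min   # max hepatic glucose release (f5)
c5     30.0     mU/L     # f5 sigmoid center (single-compartment hepatic-arm scale)
a5     0.25     L/mU     # f5 sigmoid steepness (single-compartment hepatic-arm scale)
Vp     3.0      L        # plasma insulin volume
gamma  0.2      1        # f6 exponential decay scale
c6     1.0      1        # f6 centering (f6 = 1 at 100 mg/dL)
delta  5.0      1        # f7 sigmoid steepness
c7     3.0      1        # f7 sigmoid center in f3-scaled units (~300 mg/dL)
Sb     180.0    mg/min   # f7 high-glucose asymptote (extra utilization)
Sc     4.0      mg/min   # f7 low-glucose asymptote
tau1_normal  5.0   min   # normal insulin-secretion delay
tau2_normal  25.0  min   # normal hepatic glucose-secretion delay
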