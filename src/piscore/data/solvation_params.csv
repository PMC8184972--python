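# Atomic solvation parameters (cal mol^-1 A^-2), Eisenberg & McLachlan set.
# Energy contribution of an atom = sigma(class) * ASA. Positive sigma for
# carbon means burying apolar area is favourable (negative energy change).
atom_class,sigma
C,16
N,-6
O,-6
O_charged,-24
N_charged,-50
S,21
default,0
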