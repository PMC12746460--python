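# 7-site bacteriochlorophyll Qy exciton Hamiltonian of one FMO monomer, cm^-1.
# Transcribed from the Adolphs & Renger parametrization (Biophys. J. 91, 2778 (2006)),
# as reproduced in the widely used Ishizaki & Fleming transcription (PNAS 106, 17255 (2009)).
# Diagonal entries are site energies relative to the lowest site (Bchl3); only
# energy differences enter the dynamics. Off-diagonal entries are electronic couplings.
# fixture version: 1
Bchl1	Bchl2	Bchl3	Bchl4	Bchl5	Bchl6	Bchl7
200.0	-87.7	5.5	-5.9	6.7	-13.7	-9.9
-87.7	320.0	30.8	8.2	0.7	11.8	4.3
5.5	30.8	0.0	-53.5	-2.2	-9.6	6.0
-5.9	8.2	-53.5	110.0	-70.7	-17.0	-63.3
6.7	0.7	-2.2	-70.7	270.0	81.1	-1.3
-13.7	11.8	-9.6	-17.0	81.1	420.0	39.7
-9.9	4.3	6.0	-63.3	-1.3	39.7	230.0
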