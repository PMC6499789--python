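# medexsim network v1
# n_species=2
# n_mediators=2
# inhibition_law=linear
# facilitation_law=monod
# moser_n=1.0
# c_th=0.0
# consumption=growth_coupled
# r0=0.12,0.08
# decay=0.0,0.0
kind,species,mediator,value,k,depletable
production,0,0,0.1,,
production,1,1,0.1,,
influence,0,1,0.2,10000.0,False
influence,1,0,0.2,10000.0,False
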