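# Minimal reversible heterodimerization: A(a) + B(b) <-> A(a!1).B(b!1)
begin model
begin molecule types
  A(a)
  B(b)
end molecule types
begin seed species
  A(a) 100
  B(b) 100
end seed species
begin observables
  free_molecule A_free A
  free_molecule B_free B
  bond_count AB_bonds R1
end observables
begin reaction rules
  R1: A(a) + B(b) <-> A(a!1).B(b!1) 0.01, 1.0
end reaction rules
end model
simulate({t_end=>10.0, n_steps=>50, n_runs=>20, seed=>7})
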