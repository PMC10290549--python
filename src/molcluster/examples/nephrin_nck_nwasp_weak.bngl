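# Nephrin/Nck/NWASP multivalent clustering example (weak affinity).
# Copy numbers balance binding-site stoichiometry:
#   180 Nephrin x 3 pY = 540 = 540 Nck x 1 SH2
#   540 Nck x 3 SH3 = 1620 = 270 NWASP x 6 PRM
begin model
begin parameters
  kon 1e-7
  koff 0.01
end parameters
begin molecule types
  Nephrin(y1,y2,y3)
  Nck(sh2,sh3a,sh3b,sh3c)
  NWASP(p1,p2,p3,p4,p5,p6)
end molecule types
begin seed species
  Nephrin(y1,y2,y3) 180
  Nck(sh2,sh3a,sh3b,sh3c) 540
  NWASP(p1,p2,p3,p4,p5,p6) 270
end seed species
begin observables
  free_molecule Nephrin_free Nephrin
  free_molecule Nck_free Nck
  free_molecule NWASP_free NWASP
  total_clusters Clusters
end observables
begin reaction rules
  R01: Nephrin(y1) + Nck(sh2) <-> Nephrin(y1!1).Nck(sh2!1) kon, koff
  R02: Nephrin(y2) + Nck(sh2) <-> Nephrin(y2!1).Nck(sh2!1) kon, koff
  R03: Nephrin(y3) + Nck(sh2) <-> Nephrin(y3!1).Nck(sh2!1) kon, koff
  R04: Nck(sh3a) + NWASP(p1) <-> Nck(sh3a!1).NWASP(p1!1) kon, koff
  R05: Nck(sh3a) + NWASP(p2) <-> Nck(sh3a!1).NWASP(p2!1) kon, koff
  R06: Nck(sh3a) + NWASP(p3) <-> Nck(sh3a!1).NWASP(p3!1) kon, koff
  R07: Nck(sh3a) + NWASP(p4) <-> Nck(sh3a!1).NWASP(p4!1) kon, koff
  R08: Nck(sh3a) + NWASP(p5) <-> Nck(sh3a!1).NWASP(p5!1) kon, koff
  R09: Nck(sh3a) + NWASP(p6) <-> Nck(sh3a!1).NWASP(p6!1) kon, koff
  R10: Nck(sh3b) + NWASP(p1) <-> Nck(sh3b!1).NWASP(p1!1) kon, koff
  R11: Nck(sh3b) + NWASP(p2) <-> Nck(sh3b!1).NWASP(p2!1) kon, koff
  R12: Nck(sh3b) + NWASP(p3) <-> Nck(sh3b!1).NWASP(p3!1) kon, koff
  R13: Nck(sh3b) + NWASP(p4) <-> Nck(sh3b!1).NWASP(p4!1) kon, koff
  R14: Nck(sh3b) + NWASP(p5) <-> Nck(sh3b!1).NWASP(p5!1) kon, koff
  R15: Nck(sh3b) + NWASP(p6) <-> Nck(sh3b!1).NWASP(p6!1) kon, koff
  R16: Nck(sh3c) + NWASP(p1) <-> Nck(sh3c!1).NWASP(p1!1) kon, koff
  R17: Nck(sh3c) + NWASP(p2) <-> Nck(sh3c!1).NWASP(p2!1) kon, koff
  R18: Nck(sh3c) + NWASP(p3) <-> Nck(sh3c!1).NWASP(p3!1) kon, koff
  R19: Nck(sh3c) + NWASP(p4) <-> Nck(sh3c!1).NWASP(p4!1) kon, koff
  R20: Nck(sh3c) + NWASP(p5) <-> Nck(sh3c!1).NWASP(p5!1) kon, koff
  R21: Nck(sh3c) + NWASP(p6) <-> Nck(sh3c!1).NWASP(p6!1) kon, koff
end reaction rules
end model
simulate({t_end=>30.0, n_steps=>60, n_runs=>10, seed=>1})
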