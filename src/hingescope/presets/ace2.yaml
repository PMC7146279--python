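# Region preset for the ACE2 catalytic domain, author numbering of PDB
# entries 1R4L (inhibitor-bound, closed) and 1R42 (free, open), chain A.
# Lip residue sets come from the sequence-level correspondence with the
# somatic-ACE lips. ACE2 subdomain boundaries are an APPROXIMATE
# contiguous partition analogous to the sACE subdomain layout, supplied
# to anchor hinge-angle superpositions; the lips are the authoritative
# part of this preset.
chain_id: A
lip1:
  - [54, 81]
  - [289, 296]
  - [340, 346]
  - [361, 370]
lip2:
  - [109, 131]
  - [143, 156]
  - [267, 276]
subdomain1:
  - [19, 102]
  - [289, 435]
  - [531, 563]
subdomain2:
  - [103, 288]
  - [436, 530]
  - [564, 615]
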