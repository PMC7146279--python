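# Region preset for the C domain of human somatic ACE, in the author
# numbering of PDB entry 4APH (chain A).
# Lips flank the active-site cleft; subdomain I carries the N-terminus
# and the zinc site, subdomain II the C-terminus.
chain_id: A
lip1:
  - [73, 100]
  - [297, 304]
  - [348, 354]
  - [370, 379]
lip2:
  - [128, 150]
  - [160, 173]
  - [284, 293]
subdomain1:
  - [40, 122]
  - [297, 437]
  - [551, 583]
subdomain2:
  - [123, 296]
  - [438, 550]
  - [584, 625]
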