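# Crystal-structure inputs (manual download)

The crystal-structure acceptance tests expect the PDB entries 4APH
(somatic ACE C domain with angiotensin II), 1R4L (ACE2, inhibitor
bound, closed) and 1R42 (ACE2, free, open) in this directory as
`4APH.pdb`, `1R4L.pdb`, `1R42.pdb`:

```sh
for id in 4APH 1R4L 1R42; do
  curl -o $id.pdb https://files.rcsb.org/download/$id.pdb
done
```

These files are not distributed with the package. All other tests run
without them.
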