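# Deposited-entry cache

Place plain-text PDB files here as `<id>.pdb` (lower-case), e.g.
`5hoy.pdb`. Where a network is available, populate the cache with:

```sh
turnprint fetch 5hoy 3moq 2lmn 2lmo 5aef 2beg 2mxu
```

The acceptance script (`scripts/acceptance.py`) and the deposited-entry
acceptance tests read from this directory and never modify it.
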