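Deposited coordinate sets used by the reference-reproduction tests in
tests/test_acceptance.py. They are not distributed with the package;
download them from the Protein Data Bank (https://files.rcsb.org/download/)
and place them here as <id>.pdb or <id>.cif (lower-case id):

  2lyz  lysozyme                (1001 non-H atoms, Dmax 50.6 A)
  1gip  B-DNA dodecamer, NMR    (486,  44.1)
  1btc  beta-amylase + beta-CD  (beta-CD ligand: 66, 12.6)
  3v03  BSA                     (chain A: 4385, 87.2)
  1i10  L-lactate dehydrogenase (10272, 98.6)
  6z6u  apo-ferritin            (assembly 1: 35304, 133.6)
  1a34  STMV                    (assembly 1: 81960, 181.5)

Without these files the corresponding tests fail with a pointer to this
directory; all other tests run on generated fixtures.
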