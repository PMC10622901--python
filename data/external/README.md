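# External reference inputs (not redistributed)

Three checks in `tests/test_acceptance.py` compare against published
reference structures and sequences that this repository does not
redistribute.  To run them, download the files below into this directory;
without them those three tests fail with a pointer here.

| file | source |
| --- | --- |
| `AF-Q13542-F1.pdb` | AFDB model of human 4E-BP2, <https://alphafold.ebi.ac.uk/files/AF-Q13542-F1-model_v4.pdb> (rename) |
| `2mx4.pdb` | Solution structure of phosphorylated 4E-BP2, <https://files.rcsb.org/download/2MX4.pdb> |
| `AF-O95076-F1.pdb` | AFDB model of human ALX3, <https://alphafold.ebi.ac.uk/files/AF-O95076-F1-model_v4.pdb> (rename) |
| `O95076.fasta` | UniProt sequence of ALX3, <https://rest.uniprot.org/uniprotkb/O95076.fasta> |

Everything else in the test suite and in `scripts/acceptance.py` is
self-contained and needs no downloads.
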