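# External acceptance inputs (not distributed)

The worked-example acceptance tests need real structures and annotations
that cannot be redistributed with this repository and cannot be fetched in
an offline environment. To enable them, place here:

- `1hrk.pdb` — human ferrochelatase, from
  `https://files.rcsb.org/download/1HRK.pdb`
- `1uok.pdb` — oligo-1,6-glucosidase, from
  `https://files.rcsb.org/download/1UOK.pdb`
- `pw79_sites.tsv` — catalytic-site annotation TSV (columns
  `structure_id  chain  resnum  icode  site_id  aa`, tab-separated, `#`
  comments) for a reference enzyme set, derived from the Catalytic Site
  Atlas, plus one `<structure_id>.pdb` per listed entry.

When these files are absent the corresponding tests fail with a pointer to
this document rather than silently passing.
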