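# garfinder

Find and characterize **glycine- and arginine-rich (GAR) motifs** in protein
sequences.

GAR motifs (also called RGG boxes) are low-complexity regions built from
arginine–glycine (RG) and arginine–glycine–glycine (RGG) repeat units.  They
are hallmarks of nucleolar proteins such as fibrillarin, nucleolin and GAR1
and of many RNA-binding proteins (the FET family, hnRNPs, and others), where
they carry arginine methylation sites and contribute to RNA binding and
liquid–liquid phase separation.  `garfinder` is for anyone who needs to
locate these motifs systematically — in a single protein, a batch of
orthologues, or a whole proteome — and to compare their composition.

## The motif model

A motif is a maximal chain of **anchor units**, each an arginine immediately
followed by at least one glycine (`RG` if followed by exactly one
motif-internal G, `RGG` if by two or more).  The residues strictly between
two consecutive anchor arginines must match the bounded gap grammar

```
G(1,2) - G(0,3) - X(0,5) - G(0,3) - X(0,1)
```

where `X` is any residue and `(lo,hi)` bounds the repeat count of each slot.
The grammar admits at most 14 residues between chained arginines, of which
at most 6 may be non-glycine, so it tolerates both long polyglycine tracts
(13 G in a row occur in the human fibrillarin domain) and short stretches of
other residues between units.  A motif needs at least two units — the
shortest reportable form is `RGRG` — plus leading context matching
`G(0,3)-X(0,1)` and at most two trailing glycines.  Arginines *not* followed
by glycine ("bare" Rs) are ordinary residues absorbed by wildcard slots.

Per motif, the report gives the RG and RGG unit counts, the non-G/R ("else")
residues, the motif's coverage of the polypeptide (Total%), the G/R ratio,
and the percentages of G, R and other residues.  Batch runs add totals and
the data behind an RG/RGG pie chart and a non-GR residue bar graph.  A
census mode filters long motifs (≥ 10 RG+RGG units by default) and labels
each as RG-rich or RGG-rich plus its classic tri-RGG/di-RGG/tri-RG/di-RG
repeat class.

## Worked example

Scan the 73-residue GAR domain of human fibrillarin:

```sh
$ garfinder scan fbl.fasta
>NP_001427.2 fibrillarin GAR domain [Homo sapiens]
motif 1
  position: 1..73
  pattern: PRGGGFGGRGGFGDRGGRGGRGGFGGGRGRGGGFRGRGRGGGGGGGGGGGGGRGGGGFHSGGNRGRGRGGKRG
  RG: 6  RGG: 9
  else: 'P': 1, 'F': 5, 'D': 1, 'H': 1, 'S': 1, 'N': 1, 'K': 1
  Total%: 100.0  G/R: 3.1  G%: 64.4  R%: 20.5  Non-GR%: 15.1
[PRGGGFGGRGGFGDRGGRGGRGGFGGGRGRGGGFRGRGRGGGGGGGGGGGGGRGGGGFHSGGNRGRGRGGKRG]
```

One motif covers the whole input: 6 RG and 9 RGG units, glycine outnumbering
arginine about 3:1 (G/R 3.1), with phenylalanine the most common intervening
residue — the composition typical of nucleolar GAR domains.  The final line
echoes the sequence with the motif bracketed.  `--csv`, `--txt` and
`--chart` write the table, text report and chart data to files;
`garfinder census` produces the long-motif table with richness and repeat
class columns; `garfinder fixtures` dumps the packaged reference motif sets
(`T2` — fibrillarin/nucleolin/GAR1 across five vertebrates, `T3` — 16 human
RG/RGG-repeat proteins, `T4` — long motifs from a human proteome census) as
FASTA; `garfinder simulate` emits random grammar-valid motifs for testing.

The same pipeline is available as a library:

```python
from garfinder import ProteinRecord, scan_record
hit = scan_record(ProteinRecord("demo", "", "HRGRGRGRGRGRGRGRGRGRGG")).hits[0]
hit.stats.rg_count, hit.stats.rgg_count, hit.stats.g_pct   # (9, 1, 50.0)
```

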