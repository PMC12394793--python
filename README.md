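# lipopept

MS/MS identification and quantification of **lipidated peptides** — long-chain
*S*-acylated (myristoyl/palmitoyl/stearoyl on cysteine via a labile thioester)
and prenylated (farnesyl/geranylgeranyl via a thioether) — without acyl-biotin
exchange or metabolic labeling.

Lipid PTMs shed their modification as a neutral during activation, so a
standard search that ignores neutral-loss ions wastes most of the evidence in
the spectrum. `lipopept` models those channels explicitly:

- **CID/HCD** cleave the thioester: the acyl group leaves as a ketene
  (C<sub>16</sub>H<sub>30</sub>O, 238.2297 Da for palmitoyl), giving precursor
  loss ions (p\*), fragment loss ions (y\*/b\*) that still carry sequence
  information, and a low-mass acylium diagnostic ion d\* (239.2369 *m/z* for
  palmitoyl).
- **ETD** leaves the thioester intact but cleaves the cysteine S–C bond,
  losing acyl+sulfur radicals (C<sub>16</sub>H<sub>30</sub>OS˙ 270.20 Da,
  C<sub>16</sub>H<sub>31</sub>OS˙ 271.21 Da for palmitoyl) from precursor and
  z˙ ions.
- **Prenyl** groups are lost intact (204.1878 / 272.2504 Da) from b, y and
  precursor ions; geranylgeranyl additionally sheds a partial
  C<sub>10</sub>H<sub>16</sub> fragment (136.1252 Da).

On top of the fragment model sit: spectrum annotation with backbone **ion
coverage**, **site localization** of labile modifications by site-determining
ions, a miniature variable-modification **database search** with
reversed-decoy FDR (q-values), and an MS1 **XIC stability assay** (peak-area
integration, normalization to control, t-test / ANOVA + Tukey HSD).  A
synthetic-fixture module generates spectra and chromatograms with known
ground truth, so everything is testable offline.

## Worked example

Theoretical HCD fragments for a palmitoylated tryptic peptide at charge 2:

```bash
$ lipopept fragment --peptidoform "GC[palmitoyl]AVLK/2" --activation HCD | head -9
peptidoform	series	index	charge	losses	theoretical_mz	label
GC[palmitoyl]AVLK	b	1	2	-	29.51801	b1^2+
GC[palmitoyl]AVLK	b	1	1	-	58.02874	b1
GC[palmitoyl]AVLK	y	1	2	-	74.06004	y1^2+
GC[palmitoyl]AVLK	b	2	2	C16H30O	81.02260	b2*^2+
GC[palmitoyl]AVLK	b	3	2	C16H30O	116.54116	b3*^2+
GC[palmitoyl]AVLK	y	2	2	-	130.60207	y2^2+
GC[palmitoyl]AVLK	y	1	1	-	147.11280	y1
GC[palmitoyl]AVLK	b	2	1	C16H30O	161.03792	b2*
```

Every b/y ion whose span covers Cys2 gets a `*` companion 238.2297/z lower
(the C16H30O ketene loss); y1–y4 do not reach the modified residue and so
have no loss variant.  Further down the table sit the precursor species
(p, p±H2O, p\*) and the palmitoyl diagnostic `d*` at 239.2369 *m/z*.

Other subcommands: `annotate` (peak-level TSV with ppm errors and ion
coverage), `localize` (ranks site assignments, reports the delta score),
`search` (FASTA + spectra → PSM TSV with q-values), `quantify` (run list →
areas, normalized values, adjusted p-values), `simulate` (writes the
synthetic fixture bundle).  The same operations are importable from
`lipopept` as plain functions.

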