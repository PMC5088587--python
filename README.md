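# tifykit

A toolkit for the standard analysis arc of a plant transcription-factor gene
family, built around the TIFY family of Moso bamboo and its relatives in the
grass BEP clade.  TIFY proteins — putative transcription factors central to
jasmonate signalling and abiotic-stress response — fall into four
subfamilies defined purely by domain architecture: every member carries a
TIFY domain with the conserved TIF[F/Y]XG hexamer; **JAZ** proteins add a
C-terminal Jas motif (SLX₂FX₂KRX₂RX₅PY), **ZML** proteins a CCT motif and a
C2C2-GATA zinc finger, **PPD** proteins an N-terminal PPD domain, and the
**TIFY** subfamily carries the TIFY domain alone.

The package is for researchers who want each step of a genome-wide
gene-family characterization as a tested, scriptable unit:

- **`sequence_io`** — FASTA, family-catalog, exon-table and count-matrix
  readers/writers (a 24-gene bamboo TIFY catalog ships with the package).
- **`motifs`** — consensus/PSSM motif scanning, domain architectures,
  subfamily classification, motif-logo frequency matrices, EST evidence.
- **`homology`** — Smith–Waterman alignment (BLOSUM62, affine gaps),
  Karlin–Altschul E-values, reciprocal-best-hit orthologues (E < 1e-10,
  score > 200, positives > 70%) and paralogues (E < 1e-50, positives > 80%).
- **`phylogeny`** — p/Poisson distances, Neighbor-Joining (exact on additive
  matrices), column-resampling bootstrap supports, Newick output, clade
  labeling.
- **`molevol`** — NG86 Ka/Ks: degeneracy-based site counting,
  pathway-averaged difference counting, Jukes–Cantor correction
  K = −¾ ln(1 − 4p/3), selection classes (ω ≶ 1), and molecular-clock dating
  T = K̄s/(2λ) with λ = 6.5 × 10⁻⁹ synonymous substitutions/site/year.
- **`expression`** — RPKM, log2-RPKM level bins (> 4 high, [1, 4] moderate),
  fold-change > 2 stress-response calls, 2^−ΔΔCt qPCR quantification.
- **`simulate`** — a synthetic-data generator that emulates the whole study
  design (motif-planted families, codon pairs at controlled Ka/Ks, a
  three-genome duplication/orthology scenario, negative-binomial count
  matrices, qPCR tables) with the planted truth recorded.
- **`tifykit`** (CLI) — `simulate`, `identify`, `phylo`, `orthologs`,
  `kaks`, `express`, `all`, driven by one YAML config.

## Worked example

```python
import numpy as np
from tifykit import molevol, motifs, simulate

models = motifs.default_motif_models()
cfg = simulate.FamilySimConfig(seed=1)
rng = np.random.default_rng(cfg.seed)

# a JAZ-subfamily member with planted motifs, plus its CDS
protein, cds, truth = simulate.simulate_member("JAZ", cfg, rng)
arch = motifs.scan_motifs(protein, models)
print("architecture:", [(h.motif, h.start, h.end) for h in arch.hits])
print("subfamily:", motifs.classify_subfamily(arch))
print("hexamer:", motifs.extract_tify_hexamer(arch, protein))

# evolve a paralog at Ks 0.22, omega 0.5, then estimate back
derived, _ = simulate.evolve_codons(cds.residues, 0.22, 0.11, rng,
                                    truth.protected_aa)
aln = molevol.thread_codon_alignment(
    protein.residues, simulate.translate_cds(derived), cds.residues, derived)
res = molevol.kaks(aln)
print(f"Ks={res.Ks:.4f} Ka={res.Ka:.4f} omega={res.omega:.3f} "
      f"({molevol.selection_class(res.omega)})")
print(f"T = {molevol.divergence_time([res.Ks]).T_mya} MYA")
```

prints

```
architecture: [('TIFY', 114, 119), ('Jas', 219, 237), ('TIFY', 220, 225)]
subfamily: JAZ
hexamer: TIFFDG
Ks=0.2279 Ka=0.1079 omega=0.474 (purifying)
T = 17.5 MYA
```

The scanner found the planted TIFY domain at residues 114–119 and the Jas
motif near the C terminus (plus a weak secondary TIFY-like window inside the
Jas motif — Jas resembles the CCT/TIFY neighbourhood, and classification
uses motif presence, not hit counts).  The NG86 estimate recovers the
planted divergence (K̂s 0.228 vs 0.22) and ω < 1 reports the purifying
selection the pair evolved under; at the grass synonymous clock this Ks
corresponds to a duplication ~17.5 million years ago.

The same analysis end to end, from the shell:

```bash
tifykit --seed 1 --outdir out all
```

writes `out/catalog/` (family catalog + architectures), `out/phylo/`
(bootstrapped NJ tree in Newick), `out/homology/` (orthologue/paralogue
pairs), `out/kaks/` (Ka/Ks table + dating), `out/expression/` (RPKM, calls,
summary) and `out/manifest.json`.  Reruns with the same seed and config are
byte-identical.

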