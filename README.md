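# gpmap

Genotype–phenotype map architecture of transcription-factor (TF) binding
sites, built from protein-binding-microarray (PBM) E-score data.

Each *genotype* is a double-stranded 8-bp DNA site (an 8-mer merged with
its reverse complement); its *phenotype* is the set of TFs it binds
specifically (E-score above a threshold, default τ = 0.35).  The package

* constructs the complete genotype space graph Ω — 32,896 canonical
  sites connected by single point mutations and one-base shift indels
  (523,728 edges) — and reproduces its exact statistics (diameter 8,
  characteristic path length 4.385, clustering 0.123, assortativity
  0.006, 96 % of nodes at the maximal degree 32);
* reads UniPROBE/CIS-BP-style E-score tables and TF metadata, derives
  per-phenotype genotype sets and their dominant genotype networks, and
  computes intranetwork statistics (diameter, characteristic path
  length, clustering coefficient, degree assortativity, route factor to
  the highest-affinity site);
* computes internetwork measures: overlap matrices, local mutational
  spectra and φ / Φ mutational connectivity, phenotypic accessibility,
  Bhattacharyya similarity of mutational neighborhoods and the
  neutral-neighbor similarity ratio, the interface with unbound sites,
  phenotype space covering curves (neutral and non-neutral variants),
  phenotype-network edge lists, and DNA-binding-domain coarse-graining;
* provides a size-preserving null model (random reassignment of sites
  to TFs) with null-distribution summaries;
* supports an in-vivo analysis: DNase-footprint filtering against
  promoters, putative binding-site assignment, Shannon diversity of
  allele frequencies (from VCF), and size-controlled partial Spearman
  correlations between network structure and diversity;
* ships synthetic-data generators (motif-centered E-score landscapes,
  footprints with planted sites, SNP frequencies with planted
  diversity–structure effects) so the whole pipeline runs and is tested
  without any external download.

## Command line

```bash
gpmap report --k 8                        # whole-space statistics
gpmap space build --k 8 --out edges.tsv --nodes nodes.tsv
gpmap synth --n-tfs 10 --seed 3 --outdir data/ --invivo --effect-l 0.2
gpmap load  --escores data/escores.tsv --meta data/meta.tsv
gpmap intra --escores data/escores.tsv --meta data/meta.tsv --out intra.tsv \
            --tau-grid 0.38,0.42
gpmap inter --escores data/escores.tsv --meta data/meta.tsv \
            --level tf --outdir inter/ --covering
gpmap null  --escores data/escores.tsv --reps 1000 --seed 17 --out null.tsv
gpmap invivo --footprints data/footprints.bed --genome data/genome.fa \
             --promoters data/promoters.bed --vcf data/snps.vcf \
             --escores data/escores.tsv --outdir invivo/
gpmap run --config cfg.yaml --outdir run1/   # full pipeline + manifest
```

E-score inputs are tab-separated, either a wide matrix
(`8mer  TF1  TF2 ...`) or per-TF UniPROBE-style files
(`8mer  8mer_rc  E-score`), auto-detected.  All randomness is routed
through explicit seeds; reruns with the same config and seed produce
byte-identical outputs.

## Layout

```
src/gpmap/
  space.py         canonical sites, mutation model, Ω construction
  graphs.py        CSR graph routines (batched bitset BFS, Eq-specific
                   clustering/assortativity)
  pbm_io.py        E-score tables, thresholds, genotype sets, metadata
  networks.py      genotype networks and intranetwork statistics
  internetwork.py  overlap/interface measures, covering, coarse-graining
  nullmodel.py     size-preserving randomization and null summaries
  diversity.py     footprints, site assignment, Shannon diversity,
                   structure–diversity correlations
  synthetic.py     synthetic E-score and in-vivo data generators
  cli.py           click-based pipeline CLI
tests/             pytest suite; tests/bruteforce.py holds independent
                   brute-force oracles; tests/test_acceptance.py covers
                   the acceptance criteria
```
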