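# memtopo

A trainable toolkit for α-helical membrane-protein structure prediction
from sequence, with three engines:

- **Helix segmentation** (`memtopo.propensity` + `memtopo.tmh`) —
  multi-scale sliding-window profile features (W = 13 and 15) feed an
  optimized evidence-theoretic K-nearest-neighbor classifier; the
  per-residue propensity track is median-filtered and segmented with a
  dynamic rising-threshold procedure that splits merged helices at
  interior valleys.
- **Inter-helix residue contacts** (`memtopo.contact`) — an unsupervised
  coevolution engine (sequence-weighted indicator covariance over the
  alignment, shrinkage, L1-penalized sparse precision, average-product
  correction) rank-fused with a supervised ensemble of
  evidence-theoretic KNN classifiers trained on random under-samplings
  of the non-contact class.
- **Relative accessible surface area** (`memtopo.rasa`) — a
  segment-template similarity engine (cosine match of profile windows
  against a pool of solved tracks) fused with an epsilon-insensitive
  kernel regression by a knowledge rule: confident template matches
  override the learned model.

Because the original structure-derived training corpora are not
distributable, `memtopo.synthetic` generates seeded corpora with the
statistical structure each engine assumes: hydrophobicity-coded helices
with short loops, half (8–12 residue) and long (>35 residue) helices,
alignments with planted covarying column pairs, and accessibility tracks
with α-helical (3.6 residues/turn) periodicity. The whole pipeline is
therefore trainable and testable on a laptop.

## CLI

All subcommands accept `--help`. A minimal round trip:

```sh
# seeded synthetic corpus: FASTA + labels + planted-pair alignment
memtopo synth --out-dir data --seed 1 --n-proteins 100

# helix engine
memtopo train-tmh --fasta data/proteins.fasta \
    --intervals data/topologies.tsv --model-out models/tmh.json --seed 0
memtopo predict-tmh --fasta data/proteins.fasta \
    --model models/tmh.json --out-dir pred
memtopo eval-tmh --predicted pred/predicted_intervals.tsv \
    --observed data/topologies.tsv

# contact engine (coevolution scores from an aligned FASTA)
memtopo predict-contact --msa data/msa.fasta --out contacts.tsv
memtopo eval-contact --scores contacts.tsv \
    --truth data/planted_pairs.tsv --length 50 --topk L/5

# accessibility engine
memtopo train-rasa --fasta data/proteins.fasta --rasa data/rasa.tsv \
    --intervals data/topologies.tsv --model-out models/rasa.json
memtopo predict-rasa --fasta data/proteins.fasta --model models/rasa.json \
    --intervals data/topologies.tsv --out-dir rasa_pred
```

`predict-tmh` accepts `--pssm <file>` with a PSI-BLAST ASCII PSSM for
the query; without one it falls back to a pseudo-profile built from the
sequence alone and warns (degraded mode — profile values are normalized
with a logistic map, our choice since no normalization is standard).

## Layout

```
src/memtopo/
  seqio.py       FASTA / ASCII-PSSM / aligned-FASTA / TSV readers+writers
  synthetic.py   seeded corpus, alignment and accessibility generators
  propensity.py  window features, evidence-theoretic KNN, propensity tracks
  tmh.py         median filter, dynamic-threshold segmenter, metrics
  contact.py     coevolution engine, under-sampling ensemble, fusion, top-k
  rasa.py        template pool, kernel regression, knowledge-rule fusion
  benchmarks.py  seeded end-to-end benchmarks shared by tests and scripts
  cli.py         click-based command-line interface
```
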