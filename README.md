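# sbipred

Prediction of typed interaction events between **small-molecule drugs**
(SMDs, given as SMILES strings) and **biotech drugs** (BioDs, given as
amino-acid sequences), for computational pharmacologists screening
candidate drug–drug interactions before wet-lab follow-up.

Interaction corpora only record *positive* pairs: everything else is
unlabeled, a mix of true negatives and not-yet-annotated positives. The
package therefore combines two ideas:

1. **Multi-modal representation learning.** Each drug pair is described by
   four feature modalities — learned 1D-CNN encodings of the raw
   SMILES/sequence characters; a 1024-bit hashed linear-path fingerprint
   (SMD) plus a 1280-dimensional sequence embedding (BioD); and two network
   -topology views built from prior-knowledge graphs (drug–protein
   interactions SPI/BPI and intra-type interactions SSI/BBI), encoded as
   one-hot interaction profiles compared by Jaccard similarity

   J(A, B) = |A ∩ B| / (|A| + |B| − |A ∩ B|),

   with the high-dimensional SMD rows PCA-reduced to 512 components. One
   sigmoid multi-label DNN (512 → 256 → *K*+1 units; class 0 = no
   interaction, classes 1..*K* = event types) is trained per modality and
   the four outputs are fused by unweighted averaging.

2. **PU-sampling.** Negative training pairs are *selected*, not assumed:
   T decision trees are each trained on the positives versus a fresh
   balanced random draw from the unlabeled pool, every unlabeled pair is
   scored with each tree's positive-class probability, pairs whose mean
   score reaches a threshold θ are eliminated as suspected positives, and
   the lowest-scoring survivors form a balanced high-confidence negative
   set.

A seeded synthetic-universe generator (`sbipred.synthetic_data`) plants
learnable signal in both the structure strings and the network
neighborhoods — including a configurable fraction of *hidden positives*
left unlabeled — so every stage, including the PU-sampler's ability to
avoid hidden positives, is testable without access to a licensed drug
database.

## Worked example

Generate a synthetic universe, select negatives by PU-sampling, and run
5-fold cross-validation of the four-modality ensemble (desk-scale encoder
settings; a few minutes on one core):

```bash
sbipred simulate --out universe --seed 7
# universe written to universe: {'SMD': 120, 'BioD': 30, 'Protein': 80,
#  'SSI': 286, 'BBI': 44, 'SPI': 777, 'BPI': 242, 'SBI': 395}

sbipred sample --data universe --out sampled --seed 7 \
    --smd-max-len 96 --pca-k 64
# eliminated 0 pairs at theta=1.0
# 389 negatives written (389 positives, 3211 unlabeled)

sbipred train-eval --data universe --negatives sampled/negatives.csv \
    --out eval --folds 5 --seed 7 --smd-max-len 96 --pca-k 64 \
    --max-epochs 35 --patience 8 --batch-size 128 \
    --cnn-filters 8 --cnn-embed 24
#                     recipe fold      ACC      AUC     AUPR       F1      Pre      Rec
# CNN+FP_EMB+SPI_BPI+SSI_BBI mean 0.945279 0.962313 0.875851 0.787575 0.892378 0.705404
```

Reading the output: the universe has 120 × 30 = 3,600 candidate pairs of
which 389 are labeled positive; PU-sampling keeps the 389 least
positive-looking unlabeled pairs as negatives (1:1 balance). The metric row
is the mean over the five test folds, micro-averaged over all event-class
indicators at threshold 0.5 (AUC/AUPR are threshold-free ranking areas).
`--recipe ablation` evaluates each modality alone plus the full ensemble;
`sbipred predict` ranks the entire candidate space by the highest
event-class probability. Per-fold metrics land in `eval/metrics.csv`.

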