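# aaascreen

Automated screening for abdominal aortic aneurysm (AAA) in 3D CT
volumes: preprocessing, three volumetric CNN classifiers, stratified
cross-validated evaluation, layer-wise relevance propagation (LRP) for
decision transparency, and a heuristic that finds the abdomen so the
whole pipeline runs with no manual input.

## Who this is for

Medical-imaging researchers and engineers who want a self-contained,
inspectable reference implementation of a CT screening classifier — from
NIfTI in to per-case probabilities and relevance maps out — that runs on
a laptop CPU. Clinical CT cannot ship with the code, so a synthetic
phantom generator produces labelled abdominal volumes with ground-truth
geometry; every component is exercised end to end on phantoms.

## The method in brief

A CT volume (Hounsfield units) is windowed to [−200, 400] HU and mapped
to [−1, 1], resampled to a common voxel spacing, and a fixed-size patch
is extracted around an anchor slice at the renal-artery level — supplied
by annotation, or estimated automatically from the HU distribution along
the body axis (soft-tissue run → abdomen bounds; pelvic/rib bone peaks →
abdomen centre). A two-class softmax 3D CNN (AlexNet-, VGG-16- or
ResNet-18-style, width-scaled, ReLU throughout) classifies the patch;
a case is positive when P(AAA) ≥ 0.5 (ties positive). Evaluation uses
stratified 5-fold cross-validation and reports accuracy A, precision P,
true-positive rate TPR, false-positive rate FPR, F1 and the ROC/AUC,
with per-case pooling across folds:

    A = (TP+TN)/N,  P = TP/(TP+FP),  TPR = TP/(TP+FN),
    FPR = FP/(FP+TN),  F1 = 2·P·TPR/(P+TPR)

LRP decomposes the pre-softmax AAA score into per-voxel relevance via
the ε-rule, `R_j = x_j · [Wᵀ(R/(z+ε·sign z))]_j`, with maps normalized
by their sum; positive relevance is evidence for AAA. An AAA itself is
defined geometrically: a focal diameter increase of ≥ 50% over the
normal aortic calibre — which is also exactly how the phantom generator
decides its ground-truth labels, by measuring the vessel it built.

The networks run on a small numpy engine (im2col/FFT convolutions,
manual backprop, Adam) written for transparency: every layer exposes its
linear part, which is what exact relevance propagation needs. See
`docs/methods.md` for assumptions, parameters and limitations.

## Worked example

Generate a phantom cohort, train the desk-scale 3D ResNet with 2-fold
cross-validation (about five minutes on one CPU), and screen volumes
fully automatically:

    aaascreen phantom data/ --desk-scale --set phantom.n=60
    aaascreen train data/ runs/ --desk-scale --set phantom.n=60 --set train.k_folds=2
    aaascreen screen runs/fold_0/checkpoint.npz data/phantom_000*.nii.gz \
        --desk-scale --out screen.csv

`train` prints the pooled cross-validated metrics; the run above ends
with

    pooled metrics: {"A": 0.7166666666666667, "P": 0.7272727272727273,
                     "TPR": 0.75, "FPR": 0.32142857142857145,
                     "F1": 0.7384615384615384, "DT": 0.5,
                     "AUC": 0.7879464285714286, "TP": 24, "TN": 19,
                     "FP": 9, "FN": 8}

meaning: at the 0.5 threshold, 71.7% of the 60 pooled test cases were
called correctly, 72.7% of positive calls were true AAAs, 75% of AAAs
were found, 32% of healthy cases were falsely flagged, and the ranking
quality (probability that a random AAA case outscores a random healthy
one) was 0.79. Each fold here trains on only 30 cases — accuracy climbs
quickly with cohort size; the recovery experiment that
`scripts/acceptance.py` runs trains on 80 cases and reaches held-out
AUC above 0.93. `screen.csv` holds one row per volume:

    case_id,prob_aaa,predicted_class,abdomen_z_lower,abdomen_z_upper,status
    phantom_0000.nii.gz,0.673650,1,19,140,
    phantom_0001.nii.gz,0.723043,1,20,139,

(a volume without an abdomen yields a status message in the last column,
not a crash). Relevance maps for any case:

    aaascreen lrp runs/fold_0/checkpoint.npz data/phantom_0000.nii.gz lrp_out/ \
        --desk-scale --anchor-z 100

which writes `relevance.nii.gz` (normalized: the map sums to 1) plus
per-slice PNG overlays and a `legend.json` recording the colour
convention.

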