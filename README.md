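# focipipe

High-content time-lapse analysis of transient nuclear foci, as one tested
pipeline: a synthetic scene generator with per-cell ground truth,
illumination/background preprocessing, nuclei segmentation with
dead/mitotic-cell filtering, white top-hat focus detection, overlap-based
tracking, track-level aggregation (gap closing, longest positive run,
mean-count readout), replicate-wise Z-score hit calling against negative
controls, and the companion quantifications (Manders M1, object-based
colocalization, proximity-radius positivity, line profiles, FRAP
exponential-recovery fitting).

## Layout

| module | role |
| --- | --- |
| `focipipe.synthetic_scenes` | simulated time lapses, plates and FRAP curves with ground truth |
| `focipipe.preprocess` | vignetting division, margin crop, masked-median background subtraction, power log-log slope |
| `focipipe.nuclei` | Otsu segmentation, primary/secondary profiles, viability filtering |
| `focipipe.foci` | top-hat spot detection inside nucleus masks, prominence-based `find_maxima` |
| `focipipe.tracking` | greedy overlap linking (15 px gate), track building |
| `focipipe.aggregate` | gap closing, longest run, track summaries, position QC |
| `focipipe.score` | log2 Z-scores vs sNEG1 controls, per-siRNA means, ranks, hit calls |
| `focipipe.coloc_frap` | M1, object colocalization, PLA radius test, line profiles, FRAP fits |
| `focipipe.workbench` | plate layouts, run config, pipeline composition, CLI, design calculator |

## CLI

```sh
focipipe simulate --out sim --seed 3 --wells 4 --positions 2   # TIFFs + truth CSVs
focipipe analyze --config run.yaml                             # full pipeline
focipipe score --positions-csv positions.csv --out sirna.csv
focipipe coloc --tiff twochannel.tif
focipipe frap --csv curve.csv
focipipe report --results sirna_scores.csv
focipipe conc --stock-conc 3000 --stock-vol 5 --mix-vol 19 \
    --dilution-factor 51 --dispensed-vol 50 --medium-vol 100
```

`analyze` reads a YAML config (screen profile, crop margins, viability
thresholds, QC rules, pseudocount; unknown keys are rejected) and a
directory of `r<rep>_<well>_p<pos>.tif` stacks plus a `layout.csv`
(`plate,well,sirna,gene,role`), and writes per-position/per-siRNA CSVs and
a run-metadata JSON.

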