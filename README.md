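# topodecode

Imagined-speech EEG decoding via sequences of topographic scalp maps and
hybrid 3D-convolutional + recurrent classifiers.

The pipeline turns a multichannel EEG trial (15 frontal 10-20 channels,
2 s at 256 Hz) into a sequence of 16 color scalp-map frames (64×64 RGB,
values in [0, 1]): the trial is cut into 125 ms windows starting 4 ms
after onset, each window's per-channel mean voltage is interpolated
(inverse-distance weighting) over the projected head disk, and rendered
through a fixed symmetric colormap. Sequences are classified with one of
three architectures sharing a Conv3D(16)→Pool→Conv3D(32)→Pool→
Conv3D(64)→Pool trunk and differing in the recurrent head:

| variant      | head                                                |
|--------------|-----------------------------------------------------|
| `lstm`       | 64-unit LSTM, final state                           |
| `stack_lstm` | 64-unit LSTM (sequences) → 64-unit LSTM (final)     |
| `bilstm`     | bidirectional 64-unit LSTM, concatenated states     |

Evaluation is subject-dependent: per subject, trials are class-balanced,
split 80/20 stratified, and a fresh model is trained (Adam, categorical
cross-entropy); per-subject test accuracies are averaged across
subjects.

The models run on pure NumPy (hand-written forward/backward passes), so
everything works offline on a single CPU; a synthetic EEG generator
provides separable data for end-to-end testing without any download.

## Layout

```
src/topodecode/
  montage.py     10-20/10-10 electrode positions, head-disk projection
  topomap.py     trial -> 16-frame scalp-map sequence
  dataio.py      trial containers (.h5/.npz), balancing, stratified splits
  synthetic.py   rank-1 spatiotemporal synthetic EEG with controllable SNR
  models/        Conv3D/LSTM reference ops, trainable layers, 3 variants
  train_eval.py  training loop, accuracy metrics, experiment runner
  cli.py         command-line interface
```

## CLI

```sh
# generate a synthetic 2-class, 70-trials-per-class dataset
topodecode synth --classes 2 --trials 70 --snr 5 --seed 0 --out trials.h5

# train/evaluate subject-dependently (results.csv, metrics.json, run.log)
topodecode run --classes word_a --classes word_b --variant bilstm \
    --data trials.h5 --config cfg.yaml --out results/

# convert a BCI2020 .mat epoch file to the native container
topodecode convert-bci2020 epo.mat trials.h5
```

`cfg.yaml` may override any block (all seeds are explicit):

```yaml
schedule: {window_ms: 125, offset_ms: 4, n_frames: 16}
split: {train_fraction: 0.8, seed: 0}
training: {learning_rate: 0.0001, batch_size: 32, epochs: 50, seed: 0}
experiment: {grid_size: 64, quantize: true}
```

## Notes

- Reproducing the published dataset accuracies requires the external
  BCI2020 corpus and GPU-scale training; it is out of scope here. The
  converter above makes such a run possible offline once files are local.
- Per-trial color scaling is symmetric about 0 V with the trial's peak
  windowed amplitude, so rendered sequences are invariant to positive
  gain.
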