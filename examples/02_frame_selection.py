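"""Train the candidate-frame selector and recover contrast intervals.

The selector is a per-frame CNN (pre-trained to tell contrast-filled frames
from background) feeding a bi-directional LSTM trained with a soft-F1 loss.
From its per-frame probabilities the beginning/ending contrasting frames
(BCF/ECF) are decoded as the longest above-threshold run, and 5-10 candidate
frames are sampled from that interval.
"""

from angioscreen import frame_select as FS
from angioscreen import profiles as P

videos, truths = P.easy_video_set(30, seed=5)
selector = FS.build_and_train_selector(videos[:20], truths[:20],
                                       P.easy_selector_config(seed=5))

preds = [FS.predict_contrast(selector, v) for v in videos[20:]]
for pred, truth in list(zip(preds, truths[20:]))[:5]:
    print(f"predicted [{pred.bcf}, {pred.ecf}]  truth [{truth.bcf}, {truth.ecf}]"
          f"  candidates {pred.candidates}")

report = FS.frame_selection_report(preds, truths[20:])
print(f"\nBCF error {report['bcf_mean_error']:.2f} +/- {report['bcf_sd_error']:.2f} frames,"
      f" ECF error {report['ecf_mean_error']:.2f} +/- {report['ecf_sd_error']:.2f}")
print(f"accept rate (error <= 3 frames): {report['accept_rate']:.2f},"
      f" error rate (>= 10 frames): {report['error_rate']:.2f}")
# accept rate ~1.0 on this easy set: the whole contrast plateau is recovered
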