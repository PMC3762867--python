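"""Difference spectrograms: does the illusion-trial representation track
the video or the audio syllable?

For each McGurk-labeled combination (video v, audio a) the mean
baseline-normalized multitaper spectrogram is compared against the
matched combination with the same video (v,v) and the one with the same
audio (a,a), as the mean |difference| over -1..1 s around audio onset.
A smaller same-video statistic means the high-gamma pattern follows the
seen mouth articulation, not the heard sound.
"""
from mcgurk_ecog import SimConfig, categorize_trials, select_electrodes, simulate_dataset
from mcgurk_ecog.workflows import mcgurk_difference_analysis, preprocess_epochs

cfg = SimConfig(seed=1)  # code_carrier="video": the neural code follows the video
trials, epochs = simulate_dataset(cfg)
epochs = preprocess_epochs(epochs)
trials = categorize_trials(trials)

selection = select_electrodes(epochs)
print(f"electrodes with greatest 75-200 Hz audio-window power: {selection}")

table, test = mcgurk_difference_analysis(epochs, trials, selection)
sv, sa = table["same_video_stat"].mean(), table["same_audio_stat"].mean()
print(f"mean |difference| vs same-video matched : {sv:.2f} z-units")
print(f"mean |difference| vs same-audio matched : {sa:.2f} z-units")
print(f"Mann-Whitney U p-value                  : {test.p_value:.2e}")
print(
    "\nThe same-video differences are smaller: the illusion-condition "
    "spectrogram resembles the matched trials that share its VIDEO."
)
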