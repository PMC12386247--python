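"""Align a 1 Hz sensor stream with an image frame timestamp.

Sensors tick once a second; cameras fire on their own clock.  Linear
interpolation evaluates each channel exactly at the frame time, and
min-max normalization (against training-set extrema) puts all three
channels on [0,1] for the environment encoder.
"""

from pestfusion import generate_env_series
from pestfusion.preprocess import (assemble_sample, interpolate_sensor,
                                   stats_from_series)
import numpy as np

series = generate_env_series(duration=20, time_of_day="evening",
                             weather="foggy", seed=3)
stats = stats_from_series([series])
t_frame = 7.4   # camera fired mid-interval

temp = interpolate_sensor(series.timestamps, series.temperature, t_frame)
print(f"temperature at t={t_frame}s: {temp:.3f} C "
      f"(neighbors: {series.temperature[7]:.3f}, {series.temperature[8]:.3f})")

sample = assemble_sample(np.zeros((3, 8, 8)), np.zeros((1, 8, 8)),
                         series, t_frame, stats)
print(f"normalized env vector (temperature, humidity, light): "
      f"{np.round(sample.env, 3)}")
print("each component lies in [0,1]; light is low for a foggy evening")
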