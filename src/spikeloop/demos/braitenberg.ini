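# Braitenberg Vehicle III "Explorer": two neurons steer a disc robot
# away from obstacles.  Sensor/motor/tick rate 20 Hz; the loop spans six
# buffered hops, so the architectural reaction time is 6 * 50 ms.

music_dt = 0.05

[env]
kind = environment
arena = default
n_beams = 100
fov = 3.141592653589793
max_range = 5.0
x0 = 2.0
y0 = 2.0
theta0 = 0.7853981633974483
heading_jitter = 0.5
radius = 0.3

[adapt]
kind = adapter
adapter = hemisphere
m = 100
n = 2
normalize = ("invert_range", 5.0)

[enc]
kind = encoder
mode = regular
n_neurons = 2
v_min = 0.0
v_max = 100.0

[neurons]
kind = parrot
n_neurons = 2
delay = 0.0

[dec]
kind = decoder
mode = exp
n_neurons = 2
tau_dec = 0.1

[motor]
kind = motor
v0 = 0.4
k_v = 0.12
k_omega = 0.9

connect env.scan -> adapt.in 100
connect adapt.out -> enc.in 2
connect enc.out -> neurons.in 2
connect neurons.out -> dec.in 2
connect dec.out -> motor.in 2
connect motor.cmd -> env.cmd 2
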