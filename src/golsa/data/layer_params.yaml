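# Core model layers and their activation-equation parameters.
# coding: state  -> one unit per state
#         trans  -> one unit per ordered (from, to) state pair (n_states**2)
#         action -> one unit per action
# inhibition: linear (subtractive) or shunting (scaled by own activity)
layers:
  current-state:      {inhibition: shunting, tau: 0.5, lam: 1.0,   eps: 0.0,  coding: state}
  goal:               {inhibition: linear,   tau: 1.0, lam: 1.0,   eps: 0.0,  coding: state}
  goal-gradient:      {inhibition: linear,   tau: 1.0, lam: 1.0,   eps: 0.0,  coding: state}
  adjacent-states:    {inhibition: linear,   tau: 0.2, lam: 1.0,   eps: 0.01, coding: state}
  next-desired-state: {inhibition: linear,   tau: 1.0, lam: 0.1,   eps: 0.0,  coding: state}
  previous-state-1:   {inhibition: shunting, tau: 4.0, lam: 0.5,   eps: 0.0,  coding: state}
  previous-state-2:   {inhibition: linear,   tau: 1.0, lam: 0.001, eps: 0.0,  coding: state}
  previous-action:    {inhibition: linear,   tau: 1.0, lam: 0.001, eps: 0.0,  coding: action}
  observed-transition: {inhibition: linear,  tau: 1.5, lam: 1.0,   eps: 0.0,  coding: trans}
  desired-transition: {inhibition: linear,   tau: 1.5, lam: 1.0,   eps: 0.0,  coding: trans}
  transition-output:  {inhibition: linear,   tau: 1.5, lam: 1.0,   eps: 0.0,  coding: trans}
  action-input:       {inhibition: linear,   tau: 1.0, lam: 1.0,   eps: 0.0,  coding: action}
  action-output:      {inhibition: linear,   tau: 0.5, lam: 0.2,   eps: 0.0,  coding: action}
  # Planning-extension layers (queue and simulated state).  The store is
  # decay-free so a loaded plan survives an arbitrary idle delay.
  simulated-state:    {inhibition: linear,   tau: 0.5, lam: 1.0,   eps: 0.0,  coding: state}
  queue-input:        {inhibition: linear,   tau: 0.5, lam: 1.0,   eps: 0.0,  coding: trans}
  queue-store:        {inhibition: linear,   tau: 1.0, lam: 0.0,   eps: 0.0,  coding: trans}
  queue-output:       {inhibition: linear,   tau: 0.5, lam: 1.0,   eps: 0.0,  coding: trans}

nodes:
  oscillator:            {period: 2.0, phase: 0.0}
  state_change_inhibitor: {pulse_duration: 0.3, strength: 10.0}

simulation:
  dt: 0.01
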