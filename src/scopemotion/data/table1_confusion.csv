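,insertion,withdrawal,stop
insertion,116437,1533,1379
withdrawal,1586,107336,1757
stop,3484,4603,90812
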