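# Optional extra trigger patterns, disabled by default.
# These keywords are often cited as connectivity triggers but are not part of
# the built-in 18-pattern set; uncomment a row to enable it (the file format
# matches `brainrelex patterns dump`).
# name	regex	role_after	slots	role_slot	passive_flips
#efferent from	(?i)efferent(?:s)?\s+from\b	agent	single	-	false
#terminate in	(?i)terminat(?:e|es|ing|ed)\s+(?:\w+\s+){0,2}in\b	target	single	-	true
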