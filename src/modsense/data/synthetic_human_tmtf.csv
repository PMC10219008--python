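condition,subject,rate_hz,threshold_db
2hz,s1,2.0,-6.98
2hz,s1,3.2813,-10.21
2hz,s1,5.3836,-12.18
2hz,s1,8.8327,-13.87
2hz,s1,14.4916,-16.13
2hz,s1,23.7759,-19.1
2hz,s1,39.0084,-20.26
2hz,s1,64.0,-23.36
2hz,s2,2.0,-6.84
2hz,s2,3.2813,-9.18
2hz,s2,5.3836,-10.78
2hz,s2,8.8327,-13.44
2hz,s2,14.4916,-15.43
2hz,s2,23.7759,-18.15
2hz,s2,39.0084,-20.16
2hz,s2,64.0,-22.99
2hz,s3,2.34,-11.71
2hz,s3,3.9609,-13.58
2hz,s3,6.7046,-16.07
2hz,s3,11.3487,-18.71
2hz,s3,19.2099,-21.59
2hz,s3,32.5163,-23.3
2hz,s3,55.04,-25.49
3hz,s1,3.0,-8.64
3hz,s1,4.9508,-10.46
3hz,s1,8.1701,-13.48
3hz,s1,13.4829,-14.21
3hz,s1,22.2504,-17.35
3hz,s1,36.7191,-19.2
3hz,s1,60.5963,-22.54
3hz,s1,100.0,-24.55
3hz,s2,3.0,-6.41
3hz,s2,4.9508,-8.42
3hz,s2,8.1701,-10.65
3hz,s2,13.4829,-14.16
3hz,s2,22.2504,-14.88
3hz,s2,36.7191,-18.25
3hz,s2,60.5963,-20.48
3hz,s2,100.0,-22.05
3hz,s3,3.51,-8.45
3hz,s3,5.9819,-12.09
3hz,s3,10.1946,-15.15
3hz,s3,17.3741,-17.24
3hz,s3,29.6097,-18.97
3hz,s3,50.4622,-21.13
3hz,s3,86.0,-24.17
31hz,s1,3.0,-8.4
31hz,s1,4.9508,-10.32
31hz,s1,8.1701,-12.44
31hz,s1,13.4829,-15.62
31hz,s1,22.2504,-18.16
31hz,s1,36.7191,-20.13
31hz,s1,60.5963,-23.5
31hz,s1,100.0,-24.65
31hz,s2,3.0,-8.61
31hz,s2,4.9508,-9.35
31hz,s2,8.1701,-12.33
31hz,s2,13.4829,-14.91
31hz,s2,22.2504,-17.03
31hz,s2,36.7191,-19.42
31hz,s2,60.5963,-21.23
31hz,s2,100.0,-23.88
31hz,s3,3.51,-8.5
31hz,s3,5.9819,-10.56
31hz,s3,10.1946,-13.53
31hz,s3,17.3741,-15.22
31hz,s3,29.6097,-18.32
31hz,s3,50.4622,-20.48
31hz,s3,86.0,-22.55
314hz,s1,4.0,-8.39
314hz,s1,7.2458,-11.01
314hz,s1,13.1254,-12.12
314hz,s1,23.7759,-14.37
314hz,s1,43.0688,-17.57
314hz,s1,78.0169,-19.6
314hz,s1,141.3235,-22.62
314hz,s1,256.0,-24.14
314hz,s2,4.0,-8.16
314hz,s2,7.2458,-10.19
314hz,s2,13.1254,-12.07
314hz,s2,23.7759,-15.35
314hz,s2,43.0688,-16.82
314hz,s2,78.0169,-18.71
314hz,s2,141.3235,-21.61
314hz,s2,256.0,-23.3
314hz,s3,4.68,-8.46
314hz,s3,8.8919,-11.78
314hz,s3,16.8944,-14.14
314hz,s3,32.099,-16.0
314hz,s3,60.9875,-19.1
314hz,s3,115.875,-20.67
314hz,s3,220.16,-23.07
broadband_short,s1,4.0,-23.52
broadband_short,s1,7.2458,-22.52
broadband_short,s1,13.1254,-22.42
broadband_short,s1,23.7759,-21.56
broadband_short,s1,43.0688,-18.26
broadband_short,s1,78.0169,-16.23
broadband_short,s1,141.3235,-12.33
broadband_short,s1,256.0,-9.63
broadband_short,s2,4.0,-26.91
broadband_short,s2,7.2458,-26.75
broadband_short,s2,13.1254,-26.6
broadband_short,s2,23.7759,-24.8
broadband_short,s2,43.0688,-22.27
broadband_short,s2,78.0169,-19.97
broadband_short,s2,141.3235,-16.88
broadband_short,s2,256.0,-13.15
broadband_short,s3,4.68,-24.8
broadband_short,s3,8.8919,-23.36
broadband_short,s3,16.8944,-22.33
broadband_short,s3,32.099,-20.84
broadband_short,s3,60.9875,-17.89
broadband_short,s3,115.875,-14.35
broadband_short,s3,220.16,-10.06
broadband_long,s1,2.0,-25.87
broadband_long,s1,4.8761,-24.99
broadband_long,s1,11.888,-24.53
broadband_long,s1,28.9832,-21.65
broadband_long,s1,70.6617,-18.69
broadband_long,s1,172.2752,-14.02
broadband_long,s1,420.0117,-7.88
broadband_long,s1,1024.0,-5.08
broadband_long,s2,2.0,-25.91
broadband_long,s2,4.8761,-26.27
broadband_long,s2,11.888,-24.12
broadband_long,s2,28.9832,-21.44
broadband_long,s2,70.6617,-18.53
broadband_long,s2,172.2752,-13.12
broadband_long,s2,420.0117,-8.73
broadband_long,s2,1024.0,-6.13
broadband_long,s3,2.34,-26.73
broadband_long,s3,6.2875,-26.51
broadband_long,s3,16.8944,-25.81
broadband_long,s3,45.3949,-21.13
broadband_long,s3,121.975,-16.17
broadband_long,s3,327.7439,-12.78
broadband_long,s3,880.64,-8.4
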