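group,value
Northern,17.5
Northern,0.0
Northern,6.1
Northern,0.0
Northern,1.6
Northern,1.2
Northern,0.0
Northern,5.6
Northern,0.2
Northern,0.4
Northern,3.6
Northern,0.4
Northern,0.2
Northern,0.3
Northern,0.0
Northern,3.5
Northern,0.8
Northern,0.0
Northern,0.3
Northern,2.5
Northern,7.0
Northern,5.6
Northern,0.8
Northern,0.2
Northern,3.3
Northern,4.1
Northern,18.4
Northern,15.6
Northern,0.0
Northeastern,1.2
Northeastern,62.8
Northeastern,0.2
Northeastern,0.0
Northeastern,0.0
Northeastern,4.4
Northeastern,25.1
Northeastern,0.0
Northeastern,39.0
Northeastern,4.5
Northeastern,0.8
Northeastern,0.5
Northeastern,0.0
Northeastern,19.6
Northeastern,6.8
Northeastern,0.6
Northeastern,1.2
Northeastern,27.6
Northeastern,0.6
Northeastern,0.4
Northeastern,7.2
Northeastern,0.0
Northeastern,0.0
Northeastern,0.0
Northeastern,0.0
Northeastern,0.0
Northeastern,0.8
Northeastern,0.0
Central,2.0
Central,4.4
Central,9.3
Central,31.2
Central,0.0
Central,8.6
Central,6.0
Central,11.7
Central,3.0
Central,1.2
Central,9.6
Central,1.4
Central,21.4
Central,8.7
Central,1.2
Central,2.2
Central,35.9
Central,11.3
Central,7.6
Central,8.8
Central,1.8
Central,0.4
Eastern,16.4
Eastern,0.3
Eastern,1.3
Eastern,12.9
Eastern,29.1
Eastern,12.6
Eastern,11.4
Eastern,0.0
Eastern,118.3
Eastern,6.7
Eastern,7.8
Eastern,4.2
Eastern,1.0
Eastern,0.2
Eastern,1.3
Southern,0.1
Southern,8.4
Southern,4.2
Southern,0.0
Southern,19.7
Southern,8.4
Southern,0.0
Southern,31.3
Southern,0.0
Southern,0.0
Southern,0.3
Southern,0.0
Southern,1.5
Southern,0.0
Southern,0.0
Southern,0.0
Southern,0.0
Southern,5.5
Southern,0.0
Southern,0.0
Southern,0.0
Southern,145.2
Southern,65.8
Southern,23.2
Southern,2.4
Southern,0.0
Southern,24.6
Southern,33.8
Southern,12.0
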